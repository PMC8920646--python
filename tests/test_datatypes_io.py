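"""Containers, feature-table round trips and scan aggregation."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.io

from qustc.datatypes import (
    BENIGN,
    FEATURE_COLUMNS,
    MALIGNANT,
    LesionRecord,
    ROIMask,
    RFFrame,
    UndersampledPulseWarning,
    aggregate_scans,
    canonicalize_feature_table,
)
from qustc.io import (
    ContainerLayout,
    RFLoadError,
    load_rf_dataset,
    read_feature_table,
    write_feature_table,
    write_rf_dataset,
)


def _random_table(rng, n, with_scan=False):
    rows = []
    for i in range(n):
        row = {"lesion_id": f"L{i:03d}"}
        if with_scan:
            row["scan_label"] = "longitudinal"
        row.update({c: float(rng.uniform(0, 10)) for c in FEATURE_COLUMNS})
        row["label"] = int(i % 2)
        rows.append(row)
    return pd.DataFrame(rows)


class TestRFFrame:
    def test_rejects_empty_and_invalid(self):
        with pytest.raises(ValueError):
            RFFrame(np.empty((0, 3)), 40e6, 10e6)
        with pytest.raises(ValueError):
            RFFrame(np.zeros((4, 4)), 40e6, 10e6, sound_speed=-1)

    def test_undersampled_acquisition_warns(self):
        # a 20 MHz digitizer with a 7.5 MHz probe violates the 4x guideline
        with pytest.warns(UndersampledPulseWarning):
            RFFrame(np.zeros((8, 8)), 20e6, 7.5e6)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            RFFrame(np.zeros((8, 8)), 40e6, 10e6)  # 4x margin: no warning

    def test_axial_spacing(self):
        frame = RFFrame(np.zeros((8, 8)), 40e6, 10e6)
        assert frame.axial_spacing == pytest.approx(19.25e-6)


class TestROIMask:
    def test_requires_nonempty(self):
        with pytest.raises(ValueError):
            ROIMask(np.zeros((4, 4), dtype=bool))

    def test_shape_mismatch_is_error(self):
        mask = ROIMask(np.ones((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="does not match"):
            mask.check_congruent(np.zeros((5, 4)))


class TestLesionRecord:
    def test_label_and_scan_invariants(self):
        frame = RFFrame(np.zeros((8, 8)), 40e6, 10e6, lesion_id="a")
        mask = ROIMask(np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            LesionRecord(lesion_id="a", label=2, scans=[(frame, mask)])
        with pytest.raises(ValueError):
            LesionRecord(lesion_id="b", label=MALIGNANT, scans=[(frame, mask)])
        rec = LesionRecord(lesion_id="a", label=MALIGNANT, scans=[(frame, mask)])
        assert len(rec.scans) == 1


class TestFeatureTableIO:
    def test_roundtrip_identity(self, rng, tmp_path):
        table = _random_table(rng, 3)
        path = tmp_path / "t.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        pd.testing.assert_frame_equal(
            canonicalize_feature_table(table), back, check_exact=True
        )

    def test_missing_feature_column_is_error(self, rng, tmp_path):
        table = _random_table(rng, 3).drop(columns=["energy"])
        with pytest.raises(ValueError, match="missing columns"):
            write_feature_table(table, tmp_path / "t.csv")

    def test_unknown_column_is_error(self, rng, tmp_path):
        table = _random_table(rng, 3)
        table["bogus"] = 1.0
        with pytest.raises(ValueError, match="unknown columns"):
            write_feature_table(table, tmp_path / "t.csv")

    def test_reordered_csv_reads_canonically(self, rng, tmp_path):
        table = _random_table(rng, 3)
        path = tmp_path / "t.csv"
        shuffled = table[list(reversed(table.columns))]
        shuffled.to_csv(path, index=False)
        back = read_feature_table(path)
        assert list(back.columns)[1:17] == FEATURE_COLUMNS


class TestAggregateScans:
    def test_mean_of_two_scans(self, rng):
        t = _random_table(rng, 1, with_scan=True)
        t2 = t.copy()
        t["mbf_mean"], t2["mbf_mean"] = 0.7, 0.9
        t2["scan_label"] = "transverse"
        out = aggregate_scans(pd.concat([t, t2]))
        assert len(out) == 1
        assert out.loc[0, "mbf_mean"] == pytest.approx(0.8)

    def test_three_scan_hand_value(self, rng):
        parts = []
        for v in (1.0, 2.0, 6.0):
            t = _random_table(rng, 1, with_scan=True)
            t["contrast"] = v
            parts.append(t)
        out = aggregate_scans(pd.concat(parts))
        assert out.loc[0, "contrast"] == pytest.approx(3.0)

    def test_single_scan_identity_and_idempotence(self, rng):
        t = _random_table(rng, 4)
        once = aggregate_scans(t)
        twice = aggregate_scans(once)
        pd.testing.assert_frame_equal(once, twice)
        for c in FEATURE_COLUMNS:
            assert np.allclose(np.sort(once[c]), np.sort(t[c]))

    def test_permutation_invariant_in_scan_order(self, rng):
        t = pd.concat([_random_table(rng, 3, with_scan=True) for _ in range(3)])
        fwd = aggregate_scans(t)
        rev = aggregate_scans(t.iloc[::-1])
        pd.testing.assert_frame_equal(fwd, rev)

    def test_conflicting_labels_error(self, rng):
        t = pd.concat([_random_table(rng, 1), _random_table(rng, 1)])
        t["label"] = [0, 1]
        with pytest.raises(ValueError, match="conflicting labels"):
            aggregate_scans(t)


class TestRFContainers:
    @staticmethod
    def _records(rng, n=2):
        recs = []
        for i in range(n):
            rf = rng.standard_normal((64, 8))
            mask = np.zeros((64, 8), dtype=bool)
            mask[20:40, 2:6] = True
            frame = RFFrame(rf, 40e6, 10e6, lesion_id=f"les{i}")
            recs.append(
                LesionRecord(
                    lesion_id=f"les{i}",
                    label=MALIGNANT if i % 2 else BENIGN,
                    scans=[(frame, ROIMask(mask))],
                )
            )
        return recs

    def test_h5_roundtrip(self, rng, tmp_path):
        recs = self._records(rng)
        path = tmp_path / "ds.h5"
        write_rf_dataset(recs, path)
        back = load_rf_dataset(path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.lesion_id == b.lesion_id and a.label == b.label
            np.testing.assert_allclose(a.scans[0][0].samples, b.scans[0][0].samples)
            np.testing.assert_array_equal(a.scans[0][1].mask, b.scans[0][1].mask)

    def test_mat_two_scan_container(self, rng, tmp_path):
        rf = rng.standard_normal((64, 8))
        roi = np.zeros((64, 8))
        roi[10:30, 1:6] = 1
        data = np.empty(
            (2,),
            dtype=[("rf1", "O"), ("rf2", "O"), ("roi1", "O"), ("roi2", "O"),
                   ("class", "O"), ("id", "O")],
        )
        for i in range(2):
            data[i] = (rf, rf * 2, roi, roi, np.array([[1 - i]]), f"case{i}")
        path = tmp_path / "ds.mat"
        scipy.io.savemat(path, {"data": data})
        recs = load_rf_dataset(path)
        assert len(recs) == 2
        assert recs[0].label == MALIGNANT and recs[1].label == BENIGN
        assert len(recs[0].scans) == 2
        assert recs[0].scans[0][0].scan_label == "longitudinal"

    def test_mat_missing_field_error(self, rng, tmp_path):
        data = np.empty((1,), dtype=[("rf1", "O"), ("roi1", "O")])
        data[0] = (rng.standard_normal((16, 4)), np.ones((16, 4)))
        path = tmp_path / "bad.mat"
        scipy.io.savemat(path, {"data": data})
        layout = ContainerLayout(rf_fields=("rf1",), roi_fields=("roi1",))
        with pytest.raises(RFLoadError, match="class"):
            load_rf_dataset(path, layout)

    def test_roi_shape_mismatch_error(self, rng, tmp_path):
        data = np.empty((1,), dtype=[("rf1", "O"), ("roi1", "O"), ("class", "O")])
        data[0] = (rng.standard_normal((16, 4)), np.ones((8, 4)), 1)
        path = tmp_path / "bad.mat"
        scipy.io.savemat(path, {"data": data})
        layout = ContainerLayout(rf_fields=("rf1",), roi_fields=("roi1",))
        with pytest.raises(RFLoadError, match="shape"):
            load_rf_dataset(path, layout)
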