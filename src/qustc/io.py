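"""Readers and writers for RF containers, feature tables and reports.

Two RF container dialects are supported:

* MATLAB ``.mat`` files holding a struct array with per-lesion fields for the
  RF matrices, ROI matrices and class label (the convention used by public
  breast-RF repositories that store two scans per lesion), read through
  :func:`scipy.io.loadmat`;
* an HDF5 dialect written by this package: one group per lesion, one subgroup
  per scan with ``rf`` and ``roi`` datasets, and acquisition metadata stored
  as attributes.

Feature tables round-trip through CSV with the canonical column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .datatypes import (
    BENIGN,
    FEATURE_COLUMNS,
    LABEL_COLUMN,
    MALIGNANT,
    LesionRecord,
    ROIMask,
    RFFrame,
    canonicalize_feature_table,
)

__all__ = [
    "ContainerLayout",
    "RFLoadError",
    "load_rf_dataset",
    "write_rf_dataset",
    "write_feature_table",
    "read_feature_table",
    "write_json_report",
]


class RFLoadError(ValueError):
    """Structured load failure naming the offending field or lesion."""


@dataclass
class ContainerLayout:
    """Declarative mapping from container field names to their roles.

    Defaults follow the public two-scan-per-lesion convention: a struct array
    with fields ``rf1``/``rf2`` (RF matrices), ``roi1``/``roi2`` (paired ROI
    matrices) and an integer ``class`` label (1 = malignant).
    """

    struct_name: str = "data"
    rf_fields: tuple[str, ...] = ("rf1", "rf2")
    roi_fields: tuple[str, ...] = ("roi1", "roi2")
    label_field: str = "class"
    id_field: str = "id"
    scan_labels: tuple[str, ...] = ("longitudinal", "transverse")
    sampling_frequency: float = 40e6
    center_frequency: float = 10e6
    sound_speed: float = 1540.0
    malignant_value: int = 1

    def __post_init__(self) -> None:
        if len(self.rf_fields) != len(self.roi_fields):
            raise ValueError("rf_fields and roi_fields must pair up one-to-one")


def _as_label(raw, layout: ContainerLayout) -> int:
    return MALIGNANT if int(np.ravel(raw)[0]) == layout.malignant_value else BENIGN


def load_rf_dataset(path: str | Path, layout: ContainerLayout | None = None) -> list[LesionRecord]:
    """Load a per-lesion RF container (MAT or HDF5) into LesionRecords."""
    path = Path(path)
    if not path.exists():
        raise RFLoadError(f"no such file: {path}")
    layout = layout or ContainerLayout()
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _load_h5(path, layout)
    return _load_mat(path, layout)


def _build_record(
    lesion_id: str,
    label: int,
    pairs: list[tuple[np.ndarray, np.ndarray]],
    layout: ContainerLayout,
) -> LesionRecord:
    scans = []
    for i, (rf, roi) in enumerate(pairs):
        scan_label = (
            layout.scan_labels[i] if i < len(layout.scan_labels) else f"scan{i}"
        )
        frame = RFFrame(
            samples=rf,
            sampling_frequency=layout.sampling_frequency,
            center_frequency=layout.center_frequency,
            sound_speed=layout.sound_speed,
            lesion_id=lesion_id,
            scan_label=scan_label,
        )
        mask = ROIMask(np.asarray(roi) != 0, kind="intratumoral")
        if mask.mask.shape != frame.samples.shape:
            raise RFLoadError(
                f"lesion {lesion_id!r} scan {scan_label!r}: ROI shape "
                f"{mask.mask.shape} != RF shape {frame.samples.shape}"
            )
        scans.append((frame, mask))
    return LesionRecord(lesion_id=lesion_id, label=label, scans=scans)


def _load_mat(path: Path, layout: ContainerLayout) -> list[LesionRecord]:
    contents = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False)
    if layout.struct_name not in contents:
        raise RFLoadError(f"missing struct {layout.struct_name!r} in {path}")
    data = np.atleast_1d(contents[layout.struct_name])
    records = []
    for idx, entry in enumerate(data):
        pairs = []
        for rf_f, roi_f in zip(layout.rf_fields, layout.roi_fields):
            if not hasattr(entry, rf_f):
                raise RFLoadError(f"lesion #{idx}: missing field {rf_f!r}")
            if not hasattr(entry, roi_f):
                raise RFLoadError(f"lesion #{idx}: missing field {roi_f!r}")
            pairs.append((np.asarray(getattr(entry, rf_f), dtype=float),
                          np.asarray(getattr(entry, roi_f))))
        if not hasattr(entry, layout.label_field):
            raise RFLoadError(f"lesion #{idx}: missing field {layout.label_field!r}")
        lesion_id = (
            str(np.ravel(getattr(entry, layout.id_field))[0])
            if hasattr(entry, layout.id_field)
            else f"lesion{idx:04d}"
        )
        records.append(
            _build_record(lesion_id, _as_label(getattr(entry, layout.label_field), layout),
                          pairs, layout)
        )
    return records


def _load_h5(path: Path, layout: ContainerLayout) -> list[LesionRecord]:
    records = []
    with h5py.File(path, "r") as f:
        if "lesions" not in f:
            raise RFLoadError(f"missing group 'lesions' in {path}")
        for lesion_id in sorted(f["lesions"]):
            grp = f["lesions"][lesion_id]
            if "label" not in grp.attrs:
                raise RFLoadError(f"lesion {lesion_id!r}: missing attribute 'label'")
            label = int(grp.attrs["label"])
            pairs = []
            scan_labels = []
            for scan_name in sorted(grp):
                sg = grp[scan_name]
                for ds in ("rf", "roi"):
                    if ds not in sg:
                        raise RFLoadError(
                            f"lesion {lesion_id!r} scan {scan_name!r}: missing dataset {ds!r}"
                        )
                pairs.append((sg["rf"][()], sg["roi"][()]))
                scan_labels.append(sg.attrs.get("scan_label", scan_name))
            local = ContainerLayout(
                scan_labels=tuple(scan_labels),
                sampling_frequency=float(grp.attrs.get("sampling_frequency",
                                                       layout.sampling_frequency)),
                center_frequency=float(grp.attrs.get("center_frequency",
                                                     layout.center_frequency)),
                sound_speed=float(grp.attrs.get("sound_speed", layout.sound_speed)),
            )
            records.append(_build_record(str(lesion_id), label, pairs, local))
    return records


def write_rf_dataset(records: list[LesionRecord], path: str | Path) -> None:
    """Write LesionRecords to the package's HDF5 dialect."""
    with h5py.File(path, "w") as f:
        root = f.create_group("lesions")
        for rec in records:
            grp = root.create_group(rec.lesion_id)
            grp.attrs["label"] = rec.label
            frame0 = rec.scans[0][0]
            grp.attrs["sampling_frequency"] = frame0.sampling_frequency
            grp.attrs["center_frequency"] = frame0.center_frequency
            grp.attrs["sound_speed"] = frame0.sound_speed
            for i, (frame, mask) in enumerate(rec.scans):
                sg = grp.create_group(f"scan{i:02d}")
                sg.create_dataset("rf", data=frame.samples)
                sg.create_dataset("roi", data=mask.mask.astype(np.uint8))
                sg.attrs["scan_label"] = frame.scan_label


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a finalized feature table as CSV with canonical column order."""
    canonicalize_feature_table(table).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV, validating and reordering to canonical form."""
    table = pd.read_csv(path, float_precision="round_trip")
    return canonicalize_feature_table(table)


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
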