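"""Core data containers for intratumoral quantitative-ultrasound analysis.

The package works on raw radiofrequency (RF) echo frames: 2-D matrices with
rows indexed by axial sample (depth) and columns by scan line.  Every frame
carries the acquisition metadata needed downstream (sampling frequency,
transducer center frequency, speed of sound) plus lesion bookkeeping.  ROI
masks are binary matrices congruent with either the RF/envelope grid or the
coarser sliding-window parametric grid.

Feature tables are plain :class:`pandas.DataFrame` objects with a canonical
set of 16 feature columns (see :data:`FEATURE_COLUMNS`); helper functions
validate and aggregate them rather than wrapping them in a bespoke class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "LABEL_COLUMN",
    "PROVENANCE_COLUMN",
    "BENIGN",
    "MALIGNANT",
    "RFFrame",
    "ROIMask",
    "LesionRecord",
    "validate_feature_table",
    "canonicalize_feature_table",
    "aggregate_scans",
]

#: Canonical order of the 16 quantitative-ultrasound descriptors: six spectral
#: (mean/sd of midband fit, intercept, slope), three homodyned-K (k, mu, h),
#: three Nakagami (m, omega, alpha) and four GLCM texture features.
FEATURE_COLUMNS = [
    "mbf_mean",
    "mbf_sd",
    "int_mean",
    "int_sd",
    "sl_mean",
    "sl_sd",
    "hk_k",
    "hk_mu",
    "hk_h",
    "nakagami_m",
    "nakagami_omega",
    "nakagami_alpha",
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
]

LABEL_COLUMN = "label"
PROVENANCE_COLUMN = "provenance"

#: Label encoding: malignant is the positive class throughout (sensitivity is
#: defined on malignant cases).
BENIGN = 0
MALIGNANT = 1

#: Non-feature columns a table may carry in addition to the 16 descriptors.
_META_COLUMNS = {"lesion_id", "scan_label", LABEL_COLUMN, PROVENANCE_COLUMN}


class UndersampledPulseWarning(UserWarning):
    """Sampling rate below the ~4x center-frequency acquisition guideline."""


@dataclass
class RFFrame:
    """One raw RF scan: axial samples x scan lines plus acquisition metadata.

    Parameters
    ----------
    samples
        2-D real array, rows = axial sample index (depth), columns = scan line.
    sampling_frequency
        Digitization rate in Hz.
    center_frequency
        Transducer center frequency in Hz.
    sound_speed
        Assumed propagation speed in m/s (default 1540, soft tissue).
    lesion_id, scan_label
        Bookkeeping identifiers (e.g. ``"longitudinal"`` / ``"transverse"``).
    """

    samples: np.ndarray
    sampling_frequency: float
    center_frequency: float
    sound_speed: float = 1540.0
    lesion_id: str = ""
    scan_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or min(self.samples.shape) < 1:
            raise ValueError("RF samples must be a 2-D matrix with both dims >= 1")
        if self.sampling_frequency <= 0 or self.center_frequency <= 0:
            raise ValueError("sampling_frequency and center_frequency must be > 0")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be > 0")
        if self.sampling_frequency < 4.0 * self.center_frequency:
            # broadband RF pulses carry energy well above the carrier, so the
            # usual acquisition guideline is ~4x the center frequency (e.g. a
            # 7.5 MHz probe digitized at 20 MHz may lose information)
            warnings.warn(
                f"sampling frequency {self.sampling_frequency / 1e6:g} MHz is below "
                f"4x the center frequency ({self.center_frequency / 1e6:g} MHz); "
                "loss of information is possible",
                UndersampledPulseWarning,
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_spacing(self) -> float:
        """Axial sample spacing in meters: c / (2 fs) (two-way travel)."""
        return self.sound_speed / (2.0 * self.sampling_frequency)


@dataclass
class ROIMask:
    """Binary region-of-interest mask congruent with its target image grid."""

    mask: np.ndarray
    kind: str = "intratumoral"

    _KINDS = ("intratumoral", "bounding_box")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask must contain at least one true element")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")

    def check_congruent(self, image: np.ndarray) -> None:
        if self.mask.shape != np.shape(image):
            raise ValueError(
                f"ROI mask shape {self.mask.shape} does not match image shape "
                f"{np.shape(image)}"
            )

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """Tight bounding box (row_min, row_max, col_min, col_max), inclusive."""
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())


@dataclass
class LesionRecord:
    """All scans of one lesion together with its histological label."""

    lesion_id: str
    label: int
    scans: list[tuple[RFFrame, ROIMask]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"label must be {BENIGN} (benign) or {MALIGNANT} (malignant)")
        if len(self.scans) < 1:
            raise ValueError("a lesion must have at least one scan")
        for frame, mask in self.scans:
            if frame.lesion_id and frame.lesion_id != self.lesion_id:
                raise ValueError(
                    f"scan lesion_id {frame.lesion_id!r} != record id {self.lesion_id!r}"
                )
            mask.check_congruent(frame.samples)


def validate_feature_table(table: pd.DataFrame, *, finalized: bool = True) -> None:
    """Check the canonical feature-table contract.

    A valid table has exactly the 16 canonical feature columns (plus optional
    lesion_id / scan_label / label / provenance metadata), binary labels if
    present, and — when ``finalized`` — no missing values.
    """
    cols = set(table.columns)
    missing = [c for c in FEATURE_COLUMNS if c not in cols]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    unknown = cols - set(FEATURE_COLUMNS) - _META_COLUMNS
    if unknown:
        raise ValueError(f"feature table has unknown columns: {sorted(unknown)}")
    if LABEL_COLUMN in cols:
        labels = set(pd.unique(table[LABEL_COLUMN]))
        if not labels <= {BENIGN, MALIGNANT}:
            raise ValueError(f"labels must be binary 0/1, found {labels}")
    if finalized and table[FEATURE_COLUMNS].isna().any().any():
        bad = table[FEATURE_COLUMNS].columns[table[FEATURE_COLUMNS].isna().any()]
        raise ValueError(f"finalized table contains missing values in {list(bad)}")


def canonicalize_feature_table(table: pd.DataFrame, *, finalized: bool = True) -> pd.DataFrame:
    """Validate and reorder columns to the canonical layout."""
    validate_feature_table(table, finalized=finalized)
    meta_front = [c for c in ("lesion_id", "scan_label") if c in table.columns]
    meta_back = [c for c in (LABEL_COLUMN, PROVENANCE_COLUMN) if c in table.columns]
    return table[meta_front + FEATURE_COLUMNS + meta_back].reset_index(drop=True)


def aggregate_scans(per_scan: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-scan feature table to one row per lesion.

    Each feature becomes the arithmetic mean over that lesion's scans; the
    label is carried through and must be consistent within a lesion.
    Idempotent on tables that already have one row per lesion.
    """
    validate_feature_table(per_scan)
    if "lesion_id" not in per_scan.columns:
        raise ValueError("per-scan table must have a lesion_id column")
    if LABEL_COLUMN in per_scan.columns:
        n_labels = per_scan.groupby("lesion_id")[LABEL_COLUMN].nunique()
        conflicted = n_labels[n_labels > 1]
        if len(conflicted):
            raise ValueError(
                f"conflicting labels within lesions: {list(conflicted.index)}"
            )
    agg = {c: "mean" for c in FEATURE_COLUMNS}
    if LABEL_COLUMN in per_scan.columns:
        agg[LABEL_COLUMN] = "first"
    if PROVENANCE_COLUMN in per_scan.columns:
        agg[PROVENANCE_COLUMN] = "first"
    out = per_scan.groupby("lesion_id", sort=True).agg(agg).reset_index()
    return canonicalize_feature_table(out)
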