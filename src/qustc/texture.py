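"""Gray-level co-occurrence (GLCM) texture features of the envelope image.

The minimum bounding rectangle around the tumor mask is cut from the linear
envelope image, linearly quantized to 16 gray levels over its own range, and
directed co-occurrence matrices are accumulated at five interpixel distances
(1..5) and four angles (0, 45, 90, 135 degrees).  Contrast, correlation,
energy and homogeneity are computed from each normalized matrix and averaged
over the 20 (distance, angle) settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ROIMask

__all__ = [
    "QuantizedROI",
    "GLCM",
    "TextureFeatures",
    "quantize_roi",
    "compute_glcm",
    "glcm_features",
    "averaged_texture_features",
    "DISTANCES",
    "ANGLES",
]

DISTANCES = (1, 2, 3, 4, 5)
ANGLES = (0, 45, 90, 135)

# Pixel offset (drow, dcol) per unit distance for each angle: rows grow
# downward, so 45 degrees points up-right.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class DegenerateTextureWarning(UserWarning):
    pass


@dataclass
class QuantizedROI:
    levels: np.ndarray  # integers in 1..n_levels
    n_levels: int
    origin: tuple[int, int]  # bounding-box top-left in the source image
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.levels.min() < 1 or self.levels.max() > self.n_levels:
            raise ValueError("quantized levels out of range")


@dataclass
class GLCM:
    matrix: np.ndarray  # (L, L), sums to 1
    distance: int
    angle: int

    def __post_init__(self) -> None:
        if self.distance not in DISTANCES or self.angle not in ANGLES:
            raise ValueError(f"distance must be in {DISTANCES}, angle in {ANGLES}")
        if np.any(self.matrix < 0) or not np.isclose(self.matrix.sum(), 1.0):
            raise ValueError("GLCM must be nonnegative and normalized to sum 1")


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float  # nan when undefined (zero marginal spread)
    energy: float
    homogeneity: float

    @property
    def correlation_defined(self) -> bool:
        return np.isfinite(self.correlation)


def quantize_roi(
    envelope: np.ndarray, mask: ROIMask, n_levels: int = 16
) -> QuantizedROI:
    """Linearly scale the bounding-box crop to 1..n_levels gray levels.

    The full value range of the crop maps to the full level range; a
    constant crop maps to level 1 with a degeneracy flag.  Pixels inside the
    rectangle but outside the mask are included (the rectangle, not the
    mask, is the texture ROI).
    """
    envelope = np.asarray(envelope, dtype=float)
    mask.check_congruent(envelope)
    r0, r1, c0, c1 = mask.bounding_box
    crop = envelope[r0 : r1 + 1, c0 : c1 + 1]
    lo, hi = crop.min(), crop.max()
    if hi == lo:
        warnings.warn("constant ROI: all pixels map to level 1",
                      DegenerateTextureWarning, stacklevel=2)
        return QuantizedROI(
            levels=np.ones(crop.shape, dtype=int), n_levels=n_levels,
            origin=(r0, c0), degenerate=True,
        )
    levels = 1 + np.floor((crop - lo) * n_levels / (hi - lo)).astype(int)
    return QuantizedROI(
        levels=np.clip(levels, 1, n_levels), n_levels=n_levels, origin=(r0, c0)
    )


def compute_glcm(q: QuantizedROI, distance: int, angle: int,
                 symmetric: bool = False) -> GLCM:
    """Directed co-occurrence matrix at one (distance, angle) offset.

    Counts pairs (p, p + offset) entirely inside the ROI and normalizes to a
    probability matrix; ``symmetric`` also counts the reversed pairs.
    """
    if distance not in DISTANCES or angle not in ANGLES:
        raise ValueError(f"distance must be in {DISTANCES}, angle in {ANGLES}")
    dr, dc = (o * distance for o in _ANGLE_OFFSETS[angle])
    lv = q.levels
    rows, cols = lv.shape
    if rows <= abs(dr) or cols <= abs(dc):
        raise ValueError(
            f"ROI {lv.shape} smaller than offset ({dr}, {dc}) at distance {distance}"
        )
    r_src = slice(max(0, -dr), rows - max(0, dr))
    c_src = slice(max(0, -dc), cols - max(0, dc))
    r_dst = slice(max(0, dr), rows - max(0, -dr))
    c_dst = slice(max(0, dc), cols - max(0, -dc))
    src = lv[r_src, c_src].ravel() - 1
    dst = lv[r_dst, c_dst].ravel() - 1
    counts = np.zeros((q.n_levels, q.n_levels))
    np.add.at(counts, (src, dst), 1.0)
    if symmetric:
        np.add.at(counts, (dst, src), 1.0)
    return GLCM(matrix=counts / counts.sum(), distance=distance, angle=angle)


def glcm_features(glcm: GLCM) -> TextureFeatures:
    """Contrast, correlation, energy and homogeneity of one normalized GLCM."""
    p = glcm.matrix
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("GLCM must be normalized")
    n = p.shape[0]
    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    contrast = float(np.sum((i - j) ** 2 * p))
    energy = float(np.sum(p * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    sd_i = np.sqrt(np.sum((i - mu_i) ** 2 * p))
    sd_j = np.sqrt(np.sum((j - mu_j) ** 2 * p))
    if sd_i * sd_j == 0:
        correlation = np.nan
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p) / (sd_i * sd_j))
    return TextureFeatures(
        contrast=contrast, correlation=correlation,
        energy=energy, homogeneity=homogeneity,
    )


def averaged_texture_features(
    envelope: np.ndarray, mask: ROIMask, n_levels: int = 16,
    log_compress: bool = False, symmetric: bool = False,
) -> TextureFeatures:
    """Mean of each feature over the 20 (distance, angle) GLCMs.

    Undefined correlations are excluded from the correlation mean (error if
    all 20 are undefined).  ``log_compress`` quantizes log(1 + envelope)
    instead of the linear magnitude.
    """
    img = np.log1p(np.asarray(envelope, dtype=float)) if log_compress else envelope
    q = quantize_roi(img, mask, n_levels)
    if min(q.levels.shape) <= max(DISTANCES):
        raise ValueError(
            f"bounding box {q.levels.shape} too small for distance {max(DISTANCES)}"
        )
    feats = [
        glcm_features(compute_glcm(q, d, a, symmetric=symmetric))
        for d in DISTANCES
        for a in ANGLES
    ]
    corrs = [f.correlation for f in feats if np.isfinite(f.correlation)]
    if not corrs:
        raise ValueError("correlation undefined for all 20 GLCMs (constant ROI?)")
    if len(corrs) < len(feats):
        warnings.warn(
            f"{len(feats) - len(corrs)} of {len(feats)} correlations undefined; "
            "excluded from the average", DegenerateTextureWarning, stacklevel=2,
        )
    return TextureFeatures(
        contrast=float(np.mean([f.contrast for f in feats])),
        correlation=float(np.mean(corrs)),
        energy=float(np.mean([f.energy for f in feats])),
        homogeneity=float(np.mean([f.homogeneity for f in feats])),
    )
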