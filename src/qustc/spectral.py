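"""Sliding-window spectral parameterization of RF frames.

A Hamming window (default 2.4 mm) slides down each RF line with 87.5 %
overlap; the windowed power spectrum in dB is fitted with a straight line
over the usable band (the contiguous interval within ``band_drop`` dB of the
frame-average spectral peak):

    P(f) = I + s f,        M = I + s f0,

giving the spectral slope ``s`` (dB/MHz), intercept ``I`` (dB at f = 0) and
midband fit ``M`` (dB at the band center f0).  Frequency-dependent
attenuation tilts the measured spectrum; with an assumed linear attenuation
coefficient ``alpha`` (dB/MHz-cm, default 1.0) and one-way window depth
``d`` (cm), the compensated slope is ``s + 2 alpha d`` (round-trip factor 2)
and the midband is recomputed from it; the intercept is invariant to
attenuation and left untouched.  A ``subtract`` mode applies the term with
the opposite sign, for replicating pipelines that state the correction as
``s - 2 alpha d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .datatypes import ROIMask, RFFrame

__all__ = [
    "SpectralConfig",
    "SpectralFit",
    "ParametricImageSet",
    "windowed_power_spectrum",
    "determine_band",
    "fit_spectral_line",
    "correct_attenuation",
    "build_parametric_images",
    "roi_statistics",
    "map_mask_to_windows",
]


class DegenerateSpectrumWarning(UserWarning):
    pass


@dataclass
class SpectralConfig:
    """Windowing / regression / attenuation-correction settings."""

    window_length_mm: float = 2.4
    overlap_fraction: float = 0.875
    band_drop_db: float = 6.0
    attenuation_coefficient: float = 1.0  # dB/MHz-cm
    correction_sign: str = "compensate"  # or "subtract"
    db_floor: float = -120.0
    reference_spectrum_db: np.ndarray | None = None  # optional normalization hook

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.window_length_mm <= 0 or self.band_drop_db < 0:
            raise ValueError("window_length_mm must be > 0 and band_drop_db >= 0")
        if self.attenuation_coefficient < 0:
            raise ValueError("attenuation coefficient must be >= 0")
        if self.correction_sign not in ("compensate", "subtract"):
            raise ValueError("correction_sign must be 'compensate' or 'subtract'")

    def window_samples(self, frame: RFFrame) -> int:
        n = int(round(self.window_length_mm * 1e-3 / frame.axial_spacing))
        if n < 8:
            raise ValueError(
                f"window of {self.window_length_mm} mm is only {n} samples at this "
                "sampling rate; need >= 8"
            )
        return n


@dataclass
class SpectralFit:
    """One straight-line fit to a windowed power spectrum."""

    slope: float  # dB/MHz
    intercept: float  # dB at f = 0
    midband: float  # dB at band center
    band_center: float  # MHz
    depth_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_cm < 0:
            raise ValueError("depth must be >= 0")
        expected = self.intercept + self.slope * self.band_center
        if not np.isclose(self.midband, expected, rtol=1e-9, atol=1e-9):
            raise ValueError("midband must equal intercept + slope * band_center")


@dataclass
class ParametricImageSet:
    """MBF / INT / SL images on the sliding-window grid (windows x lines)."""

    mbf_image: np.ndarray
    int_image: np.ndarray
    sl_image: np.ndarray
    window_centers: np.ndarray  # axial sample index of each window center
    band: tuple[float, float]  # MHz
    config: SpectralConfig

    def __post_init__(self) -> None:
        shapes = {self.mbf_image.shape, self.int_image.shape, self.sl_image.shape}
        if len(shapes) != 1:
            raise ValueError("parametric images must be congruent")
        if np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window centers must be strictly increasing")

    @property
    def band_center(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])


def windowed_power_spectrum(
    segment: np.ndarray,
    sampling_frequency: float,
    window_samples: int | None = None,
    db_floor: float = -120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-tapered periodogram of one window, in dB over [0, fs/2] MHz."""
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be 1-D")
    if window_samples is not None and len(segment) != window_samples:
        raise ValueError(
            f"segment length {len(segment)} != configured window {window_samples}"
        )
    taper = np.hamming(len(segment))
    spec = np.fft.rfft(segment * taper)
    power = np.abs(spec) ** 2
    freqs_mhz = np.fft.rfftfreq(len(segment), d=1.0 / sampling_frequency) / 1e6
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    if np.any(~np.isfinite(power_db)):
        warnings.warn("zero-power bins floored", DegenerateSpectrumWarning, stacklevel=2)
        power_db = np.where(np.isfinite(power_db), power_db, db_floor)
    return freqs_mhz, np.maximum(power_db, db_floor)


def determine_band(
    freqs_mhz: np.ndarray, power_db: np.ndarray, band_drop_db: float = 6.0
) -> tuple[float, float]:
    """Contiguous interval around the spectral peak within ``band_drop_db``.

    The peak is the global maximum (ties broken toward the lowest frequency).
    A band clipped at the grid edge is returned with a warning; fewer than
    3 bins is an error.
    """
    power_db = np.asarray(power_db, dtype=float)
    peak = int(np.argmax(power_db))
    thr = power_db[peak] - band_drop_db
    lo = peak
    while lo > 0 and power_db[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(power_db) - 1 and power_db[hi + 1] >= thr:
        hi += 1
    if lo == 0 or hi == len(power_db) - 1:
        warnings.warn(
            "usable band clipped at the frequency-grid edge",
            DegenerateSpectrumWarning,
            stacklevel=2,
        )
    if hi - lo + 1 < 3:
        raise ValueError(
            "usable band narrower than 3 bins; use a longer window for finer "
            "frequency resolution"
        )
    return float(freqs_mhz[lo]), float(freqs_mhz[hi])


def fit_spectral_line(
    freqs_mhz: np.ndarray,
    power_db: np.ndarray,
    band: tuple[float, float],
    depth_cm: float = 0.0,
) -> SpectralFit:
    """Ordinary least squares of power (dB) on frequency (MHz) within a band."""
    freqs_mhz = np.asarray(freqs_mhz, dtype=float)
    f_low, f_high = band
    if f_low < freqs_mhz[0] - 1e-12 or f_high > freqs_mhz[-1] + 1e-12:
        raise ValueError(f"band {band} outside frequency grid")
    sel = (freqs_mhz >= f_low) & (freqs_mhz <= f_high)
    if sel.sum() < 3:
        raise ValueError("band must contain at least 3 frequency bins")
    f = freqs_mhz[sel]
    p = np.asarray(power_db, dtype=float)[sel]
    fbar, pbar = f.mean(), p.mean()
    slope = float(np.sum((f - fbar) * (p - pbar)) / np.sum((f - fbar) ** 2))
    intercept = float(pbar - slope * fbar)
    f0 = 0.5 * (f_low + f_high)
    return SpectralFit(
        slope=slope,
        intercept=intercept,
        midband=intercept + slope * f0,
        band_center=f0,
        depth_cm=depth_cm,
    )


def correct_attenuation(
    fit: SpectralFit, alpha_db_mhz_cm: float, sign: str = "compensate"
) -> SpectralFit:
    """Apply the linear attenuation correction 2*alpha*d to slope and midband.

    ``compensate`` adds the round-trip attenuation slope back (physical
    compensation); ``subtract`` subtracts it.  The intercept is
    attenuation-invariant and unchanged; the midband is recomputed from the
    corrected slope at the band center.
    """
    if alpha_db_mhz_cm < 0:
        raise ValueError("alpha must be >= 0")
    c = 2.0 * alpha_db_mhz_cm * fit.depth_cm
    if sign == "compensate":
        slope = fit.slope + c
    elif sign == "subtract":
        slope = fit.slope - c
    else:
        raise ValueError("sign must be 'compensate' or 'subtract'")
    return replace(fit, slope=slope, midband=fit.intercept + slope * fit.band_center)


def build_parametric_images(
    frame: RFFrame, config: SpectralConfig | None = None
) -> ParametricImageSet:
    """Slide the Hamming window down every line and assemble MBF/INT/SL images.

    The usable band is fixed per frame from the average (linear-power)
    spectrum over all windows and lines, so the band center is a single
    frame-level constant.  The attenuation correction uses the one-way depth
    of each window center measured from the first axial sample.
    """
    config = config or SpectralConfig()
    n_w = config.window_samples(frame)
    if frame.n_samples < n_w:
        raise ValueError(
            f"frame of {frame.n_samples} samples shorter than window ({n_w})"
        )
    hop = max(1, int(round(n_w * (1.0 - config.overlap_fraction))))
    starts = np.arange(0, frame.n_samples - n_w + 1, hop)
    centers = starts + n_w // 2

    # (windows, n_w, lines) stack of tapered segments -> rfft over axis 1.
    taper = np.hamming(n_w)
    segs = np.stack([frame.samples[s : s + n_w] for s in starts], axis=0)
    spec = np.fft.rfft(segs * taper[None, :, None], axis=1)
    power = np.abs(spec) ** 2
    freqs_mhz = np.fft.rfftfreq(n_w, d=1.0 / frame.sampling_frequency) / 1e6

    mean_power = power.mean(axis=(0, 2))
    with np.errstate(divide="ignore"):
        mean_db = 10.0 * np.log10(np.maximum(mean_power, 10 ** (config.db_floor / 10.0)))
    band = determine_band(freqs_mhz, mean_db, config.band_drop_db)
    f_low, f_high = band
    f0 = 0.5 * (f_low + f_high)

    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    power_db = np.where(np.isfinite(power_db), power_db, config.db_floor)
    power_db = np.maximum(power_db, config.db_floor)
    if config.reference_spectrum_db is not None:
        power_db = power_db - np.asarray(config.reference_spectrum_db)[None, :, None]

    sel = (freqs_mhz >= f_low) & (freqs_mhz <= f_high)
    f = freqs_mhz[sel]
    fbar = f.mean()
    denom = np.sum((f - fbar) ** 2)
    p = power_db[:, sel, :]
    pbar = p.mean(axis=1)
    slope = np.einsum("k,wkl->wl", f - fbar, p) / denom  # (windows, lines)
    intercept = pbar - slope * fbar

    depth_cm = centers * frame.axial_spacing * 100.0
    c = 2.0 * config.attenuation_coefficient * depth_cm[:, None]
    if config.correction_sign == "compensate":
        slope_corr = slope + c
    else:
        slope_corr = slope - c
    midband = intercept + slope_corr * f0

    return ParametricImageSet(
        mbf_image=midband,
        int_image=intercept,
        sl_image=slope_corr,
        window_centers=centers,
        band=band,
        config=config,
    )


def roi_statistics(image: np.ndarray, mask: ROIMask) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of masked pixel values."""
    mask.check_congruent(image)
    values = np.asarray(image)[mask.mask]
    if values.size == 0:
        raise ValueError("empty ROI")
    if values.size == 1:
        warnings.warn(
            "single-pixel ROI: standard deviation defined as 0",
            DegenerateSpectrumWarning,
            stacklevel=2,
        )
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1))


def map_mask_to_windows(mask: np.ndarray, window_centers: np.ndarray) -> np.ndarray:
    """Nearest-window rule: a parametric pixel inherits the RF-grid mask value
    at its window-center sample on the same line."""
    mask = np.asarray(mask, dtype=bool)
    return mask[np.asarray(window_centers)[:, None], np.arange(mask.shape[1])[None, :]]
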