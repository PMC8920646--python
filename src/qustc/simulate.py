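"""Synthetic RF data with known ground truth.

The generator emulates a linear-array acquisition: each scan line is the
convolution of a Gaussian-modulated cosine pulse with a sparse random
scatterer train.  The effective number of scatterers per resolution cell
controls where the envelope sits on the pre-Rayleigh ... Rayleigh axis (the
Nakagami ``m`` and homodyned-K ``mu`` parameters); an optional constant-
amplitude periodic scatterer component adds coherent energy (the homodyned-K
``k`` parameter); linear frequency-dependent attenuation in dB/MHz-cm tilts
the spectrum with depth.  An elliptical "tumor" region carries its own
scatterer statistics so intratumoral estimates have a known truth.

Alongside the physical simulator there are direct envelope samplers for the
Nakagami and homodyned-K distributions (used to build estimator lookup
tables and as test oracles) and a feature-table simulator that draws
two-class 16-feature tables with configurable imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.signal

from .datatypes import (
    BENIGN,
    FEATURE_COLUMNS,
    LABEL_COLUMN,
    MALIGNANT,
    PROVENANCE_COLUMN,
    ROIMask,
    RFFrame,
)

__all__ = [
    "SimConfig",
    "sample_nakagami_envelope",
    "sample_homodyned_k",
    "simulate_rf_frame",
    "simulate_lesion_dataset",
    "simulate_feature_table",
    "BENIGN_FEATURE_STATS",
    "MALIGNANT_FEATURE_STATS",
]


@dataclass
class SimConfig:
    """Acquisition + scattering parameters for one simulated RF frame.

    Defaults mirror a 10 MHz linear-array breast acquisition digitized at
    40 MHz with 512 lines, fully developed speckle outside the lesion, and
    1 dB/MHz-cm tissue attenuation.
    """

    n_lines: int = 512
    n_samples: int = 2600
    sampling_frequency: float = 40e6
    pulse_center_frequency: float = 10e6
    pulse_fractional_bandwidth: float = 0.6
    scatterers_per_resolution_cell: float = 10.0
    coherent_amplitude_ratio: float = 0.0
    attenuation: float = 1.0  # dB/MHz-cm
    sound_speed: float = 1540.0
    background_scatterers_per_cell: float = 12.0
    roi_semiaxes: tuple[float, float] = (0.30, 0.30)  # fractions of frame dims
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_lines",
            "n_samples",
            "sampling_frequency",
            "pulse_center_frequency",
            "pulse_fractional_bandwidth",
            "scatterers_per_resolution_cell",
            "sound_speed",
            "background_scatterers_per_cell",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.coherent_amplitude_ratio < 0 or self.attenuation < 0:
            raise ValueError("coherent_amplitude_ratio and attenuation must be >= 0")

    @property
    def axial_spacing(self) -> float:
        return self.sound_speed / (2.0 * self.sampling_frequency)


def sample_nakagami_envelope(
    m: float, omega: float, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` Nakagami(m, omega) envelope amplitudes.

    The intensity R^2 of a Nakagami amplitude is gamma distributed with shape
    ``m`` and mean ``omega``; amplitudes are the square root of such gamma
    variates.  ``m = 1`` gives a Rayleigh envelope.
    """
    if m <= 0 or omega <= 0:
        raise ValueError("m and omega must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return np.sqrt(rng.gamma(shape=m, scale=omega / m, size=n))


def sample_homodyned_k(
    k: float,
    mu: float,
    sigma2: float = 1.0,
    n: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` homodyned-K envelope amplitudes via the compound form.

    Conditional on a gamma-distributed local diffuse power ``g^2`` (shape
    ``mu``, mean ``sigma2``), the complex echo is a coherent phasor of
    amplitude ``s = k * sqrt(sigma2)`` plus circular complex Gaussian diffuse
    scattering of power ``g^2``; the envelope is its magnitude.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if mu <= 0 or sigma2 <= 0:
        raise ValueError("mu and sigma2 must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g2 = rng.gamma(shape=mu, scale=sigma2 / mu, size=n)
    s = k * np.sqrt(sigma2)
    re = s + np.sqrt(g2 / 2.0) * rng.standard_normal(n)
    im = np.sqrt(g2 / 2.0) * rng.standard_normal(n)
    return np.hypot(re, im)


def _gaussian_pulse(config: SimConfig) -> np.ndarray:
    """Gaussian-modulated cosine pulse sampled at the acquisition rate."""
    fs = config.sampling_frequency
    fc = config.pulse_center_frequency
    bw = config.pulse_fractional_bandwidth
    cutoff = scipy.signal.gausspulse("cutoff", fc=fc, bw=bw, bwr=-6, tpr=-60)
    t = np.arange(-cutoff, cutoff, 1.0 / fs)
    return scipy.signal.gausspulse(t, fc=fc, bw=bw, bwr=-6)


def _resolution_cell_samples(config: SimConfig) -> int:
    """Resolution cell length = pulse -6 dB envelope extent, in samples."""
    fs = config.sampling_frequency
    fc = config.pulse_center_frequency
    bw = config.pulse_fractional_bandwidth
    cutoff = scipy.signal.gausspulse("cutoff", fc=fc, bw=bw, bwr=-6, tpr=-60)
    t = np.arange(-cutoff, cutoff, 1.0 / fs)
    _, env = scipy.signal.gausspulse(t, fc=fc, bw=bw, bwr=-6, retenv=True)
    n = int(np.count_nonzero(env >= 0.5 * env.max()))
    return max(n, 1)


def _apply_depth_attenuation(
    rf: np.ndarray, fs: float, axial_spacing_m: float, alpha_db_mhz_cm: float
) -> np.ndarray:
    """Depth-varying linear-with-frequency attenuation via overlap-add STFT.

    Each half-overlapping Hann block is scaled in the frequency domain by
    10^(-(2 alpha f d)/20) with d the block-center one-way depth in cm and f
    in MHz; the factor 2 accounts for round-trip propagation.
    """
    if alpha_db_mhz_cm == 0:
        return rf
    # 128 samples keeps the depth quantization of the gain fine enough that
    # the spectral-slope depth trend reproduces -2*alpha within sampling noise
    block = 128
    hop = block // 2
    n = rf.shape[0]
    n_pad = int(np.ceil(n / hop) * hop + block)
    padded = np.zeros((n_pad, rf.shape[1]))
    padded[:n] = rf
    win = scipy.signal.get_window("hann", block, fftbins=True)
    freqs_mhz = np.fft.rfftfreq(block, d=1.0 / fs) / 1e6
    out = np.zeros_like(padded)
    for start in range(0, n_pad - block + 1, hop):
        seg = padded[start : start + block] * win[:, None]
        depth_cm = (start + block / 2.0) * axial_spacing_m * 100.0
        gain = 10.0 ** (-(2.0 * alpha_db_mhz_cm * freqs_mhz * depth_cm) / 20.0)
        out[start : start + block] += np.fft.irfft(
            np.fft.rfft(seg, axis=0) * gain[:, None], n=block, axis=0
        )
    return out[:n]


def _ellipse_mask(n_samples: int, n_lines: int, semiaxes: tuple[float, float]) -> np.ndarray:
    rows = np.arange(n_samples)[:, None]
    cols = np.arange(n_lines)[None, :]
    r0, c0 = (n_samples - 1) / 2.0, (n_lines - 1) / 2.0
    a, b = semiaxes[0] * n_samples, semiaxes[1] * n_lines
    return ((rows - r0) / a) ** 2 + ((cols - c0) / b) ** 2 <= 1.0


def simulate_rf_frame(config: SimConfig) -> tuple[RFFrame, ROIMask, dict]:
    """Simulate one RF frame with an elliptical lesion and known ground truth.

    Returns the frame, the intratumoral ROI mask on the RF grid, and a
    ground-truth record of every generating parameter.
    """
    rng = np.random.default_rng(config.seed)
    pulse = _gaussian_pulse(config)
    cell = _resolution_cell_samples(config)

    roi = _ellipse_mask(config.n_samples, config.n_lines, config.roi_semiaxes)
    density = np.where(
        roi, config.scatterers_per_resolution_cell, config.background_scatterers_per_cell
    )
    # Sum of N(0,1) amplitudes over a Poisson count is Gaussian with variance
    # equal to the count, so the reflectivity can be drawn in one shot.
    counts = rng.poisson(density / cell)
    reflectivity = rng.standard_normal(counts.shape) * np.sqrt(counts)

    if config.coherent_amplitude_ratio > 0:
        # Constant-amplitude scatterers one resolution cell apart inside the
        # lesion; amplitude k times the per-cell diffuse RMS so the coherent/
        # diffuse energy ratio tracks k.
        amp = config.coherent_amplitude_ratio * np.sqrt(
            config.scatterers_per_resolution_cell
        )
        periodic = np.zeros_like(reflectivity)
        periodic[::cell, :] = amp
        reflectivity = reflectivity + np.where(roi, periodic, 0.0)

    rf = scipy.signal.fftconvolve(reflectivity, pulse[:, None], mode="same", axes=0)
    rf = _apply_depth_attenuation(
        rf, config.sampling_frequency, config.axial_spacing, config.attenuation
    )

    frame = RFFrame(
        samples=rf,
        sampling_frequency=config.sampling_frequency,
        center_frequency=config.pulse_center_frequency,
        sound_speed=config.sound_speed,
        lesion_id=f"sim-{config.seed:06d}",
        scan_label="simulated",
    )
    truth = dict(asdict(config), resolution_cell_samples=cell, pulse_length=len(pulse))
    return frame, ROIMask(roi, kind="intratumoral"), truth


# Scatterer statistics distinguishing the two simulated lesion classes:
# malignant lesions get denser, more coherent intratumoral scattering, which
# raises the Nakagami m and homodyned-K k truths relative to benign ones.
_CLASS_SCATTERING = {
    BENIGN: {"scatterers_per_resolution_cell": 1.5, "coherent_amplitude_ratio": 0.7},
    MALIGNANT: {"scatterers_per_resolution_cell": 3.5, "coherent_amplitude_ratio": 0.9},
}


def simulate_lesion_dataset(
    n_benign: int,
    n_malignant: int,
    scans_per_lesion: int = 2,
    base_config: SimConfig | None = None,
    class_overrides: dict[int, dict] | None = None,
    seed: int = 0,
):
    """Simulate a two-class lesion dataset with multiple scans per lesion.

    Each lesion reuses one scatterer configuration across its scans (fresh
    speckle realizations per scan), mimicking intersecting scan planes of the
    same tissue.  Returns a list of LesionRecords.
    """
    from dataclasses import replace

    from .datatypes import LesionRecord

    base = base_config or SimConfig()
    overrides = class_overrides or _CLASS_SCATTERING
    children = np.random.SeedSequence(seed).spawn((n_benign + n_malignant) * scans_per_lesion)
    records = []
    counter = 0
    for label, count, tag in ((BENIGN, n_benign, "b"), (MALIGNANT, n_malignant, "m")):
        for i in range(count):
            lesion_id = f"sim-{tag}-{i:04d}"
            scans = []
            for s in range(scans_per_lesion):
                child = children[counter * scans_per_lesion + s]
                scan_seed = int(child.generate_state(1)[0]) % (2**31 - 1)
                cfg = replace(base, seed=scan_seed, **overrides[label])
                frame, mask, _ = simulate_rf_frame(cfg)
                frame.lesion_id = lesion_id
                frame.scan_label = ("longitudinal", "transverse")[s % 2] if s < 2 else f"scan{s}"
                scans.append((frame, mask))
            counter += 1
            records.append(LesionRecord(lesion_id=lesion_id, label=label, scans=scans))
    return records


# Default per-class feature statistics (mean, sd) used by the feature-table
# simulator; they mimic the separation observed between benign and malignant
# breast lesions in clinical QUS feature tables.
BENIGN_FEATURE_STATS = {
    "mbf_mean": (88.25, 6.84),
    "mbf_sd": (4.61, 0.86),
    "int_mean": (95.19, 4.25),
    "int_sd": (14.98, 0.78),
    "sl_mean": (-4.54, 0.84),
    "sl_sd": (2.09, 0.12),
    "hk_k": (0.73, 0.08),
    "hk_mu": (0.18, 0.10),
    "hk_h": (0.58, 0.03),
    "nakagami_m": (0.54, 0.06),
    "nakagami_omega": (408736.82, 134753.77),
    "nakagami_alpha": (219.74, 55.23),
    "contrast": (2.51, 1.11),
    "correlation": (0.59, 0.06),
    "energy": (0.135, 0.09),
    "homogeneity": (0.67, 0.07),
}

MALIGNANT_FEATURE_STATS = {
    "mbf_mean": (92.06, 9.25),
    "mbf_sd": (5.08, 1.19),
    "int_mean": (91.80, 6.56),
    "int_sd": (15.32, 0.76),
    "sl_mean": (-4.52, 1.01),
    "sl_sd": (2.12, 0.08),
    "hk_k": (0.84, 0.23),
    "hk_mu": (0.28, 0.26),
    "hk_h": (0.55, 0.08),
    "nakagami_m": (0.67, 0.17),
    "nakagami_omega": (189811.20, 166031.05),
    "nakagami_alpha": (119.24, 98.33),
    "contrast": (2.01, 1.02),
    "correlation": (0.61, 0.07),
    "energy": (0.18, 0.10),
    "homogeneity": (0.70, 0.08),
}

# Valid ranges each feature is truncated to after the normal draw.
_EPS = 1e-6
_FEATURE_BOUNDS = {
    "hk_k": (0.0, np.inf),
    "hk_mu": (_EPS, np.inf),
    "hk_h": (_EPS, 1.0),
    "nakagami_m": (_EPS, np.inf),
    "nakagami_omega": (_EPS, np.inf),
    "nakagami_alpha": (_EPS, np.inf),
    "contrast": (0.0, np.inf),
    "correlation": (-1.0, 1.0),
    "energy": (_EPS, 1.0),
    "homogeneity": (_EPS, 1.0),
}


def simulate_feature_table(
    n_benign: int,
    n_malignant: int,
    class_means: dict[int, dict] | None = None,
    class_sds: dict[int, dict] | None = None,
    seed: int = 0,
) -> "pd.DataFrame":
    """Draw a two-class 16-feature table with configurable imbalance.

    Features are independent normals per class (truncated to their valid
    ranges); defaults reproduce realistic benign/malignant separation.
    ``class_means``/``class_sds`` map label -> {feature: value}.
    """
    import pandas as pd

    if n_benign < 1 or n_malignant < 1:
        raise ValueError("class counts must be >= 1")
    means = class_means or {
        BENIGN: {f: s[0] for f, s in BENIGN_FEATURE_STATS.items()},
        MALIGNANT: {f: s[0] for f, s in MALIGNANT_FEATURE_STATS.items()},
    }
    sds = class_sds or {
        BENIGN: {f: s[1] for f, s in BENIGN_FEATURE_STATS.items()},
        MALIGNANT: {f: s[1] for f, s in MALIGNANT_FEATURE_STATS.items()},
    }
    for label in (BENIGN, MALIGNANT):
        for spec_map, name in ((means, "class_means"), (sds, "class_sds")):
            if set(spec_map[label]) != set(FEATURE_COLUMNS):
                raise ValueError(
                    f"{name}[{label}] must specify exactly the 16 canonical features"
                )

    rng = np.random.default_rng(seed)
    rows = []
    for label, count, tag in ((BENIGN, n_benign, "b"), (MALIGNANT, n_malignant, "m")):
        for i in range(count):
            row = {"lesion_id": f"sim-{tag}-{i:04d}"}
            for feat in FEATURE_COLUMNS:
                v = rng.normal(means[label][feat], sds[label][feat])
                lo, hi = _FEATURE_BOUNDS.get(feat, (-np.inf, np.inf))
                row[feat] = float(np.clip(v, lo, hi))
            row[LABEL_COLUMN] = label
            row[PROVENANCE_COLUMN] = "original"
            rows.append(row)
    return pd.DataFrame(rows)
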