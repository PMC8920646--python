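"""End-to-end extraction of the 16 QUS descriptors per lesion.

Per scan: the three spectral parametric images yield intratumoral mean and
standard deviation of midband fit, intercept and slope (6 values); all
intratumoral envelope samples feed the homodyned-K (k, mu, h) and Nakagami
(m, omega, alpha) fits (6 values); the bounding-box GLCM analysis yields
contrast, correlation, energy and homogeneity (4 values).  Scans of a
lesion are then averaged to one row per lesion.

:class:`QUSFeatureExtractor` is a sklearn-style transformer whose ``fit``
prepares the homodyned-K lookup table (an expensive, reusable resource) and
whose ``transform`` maps lesion records to a feature table.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    FEATURE_COLUMNS,
    LABEL_COLUMN,
    LesionRecord,
    ROIMask,
    aggregate_scans,
    canonicalize_feature_table,
)
from .envelope import (
    HKLookupTable,
    build_hk_lookup,
    compute_envelope,
    estimate_homodyned_k,
    estimate_nakagami,
)
from .spectral import (
    SpectralConfig,
    build_parametric_images,
    map_mask_to_windows,
    roi_statistics,
)
from .texture import averaged_texture_features

__all__ = ["QUSFeatureExtractor", "extract_scan_features", "extract_all_features"]

logger = logging.getLogger("qustc")


class FeatureExtractionError(RuntimeError):
    """Extraction failure annotated with lesion and scan identifiers."""


def extract_scan_features(
    frame,
    mask: ROIMask,
    spectral_config: SpectralConfig,
    hk_lookup: HKLookupTable,
    constrained_nakagami: bool = True,
    glcm_levels: int = 16,
) -> dict[str, float]:
    """The 16 descriptors of one (frame, intratumoral mask) pair."""
    envelope = compute_envelope(frame)
    pset = build_parametric_images(frame, spectral_config)
    wmask = map_mask_to_windows(mask.mask, pset.window_centers)
    if not wmask.any():
        raise ValueError("ROI does not cover any sliding-window center")
    wroi = ROIMask(wmask, kind="intratumoral")

    mbf_mean, mbf_sd = roi_statistics(pset.mbf_image, wroi)
    int_mean, int_sd = roi_statistics(pset.int_image, wroi)
    sl_mean, sl_sd = roi_statistics(pset.sl_image, wroi)

    samples = envelope[mask.mask]
    samples = samples[samples > 0]
    nak = estimate_nakagami(samples, constrained=constrained_nakagami)
    hk = estimate_homodyned_k(samples, hk_lookup)
    tex = averaged_texture_features(envelope, mask, n_levels=glcm_levels)

    return {
        "mbf_mean": mbf_mean,
        "mbf_sd": mbf_sd,
        "int_mean": int_mean,
        "int_sd": int_sd,
        "sl_mean": sl_mean,
        "sl_sd": sl_sd,
        "hk_k": hk.k,
        "hk_mu": hk.mu,
        "hk_h": hk.h,
        "nakagami_m": nak.m,
        "nakagami_omega": nak.omega,
        "nakagami_alpha": nak.alpha_scatter,
        "contrast": tex.contrast,
        "correlation": tex.correlation,
        "energy": tex.energy,
        "homogeneity": tex.homogeneity,
    }


class QUSFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform lesion records into the canonical 16-feature table.

    Parameters
    ----------
    spectral_config
        Sliding-window / attenuation-correction settings.
    hk_lookup
        Pre-built homodyned-K lookup table; built at ``fit`` time from
        ``hk_lookup_kwargs`` when absent.
    constrained_nakagami
        Clip the Nakagami shape estimate to >= 0.5.
    aggregate
        Average per-scan rows to one row per lesion (default True).
    """

    def __init__(
        self,
        spectral_config: SpectralConfig | None = None,
        hk_lookup: HKLookupTable | None = None,
        hk_lookup_kwargs: dict | None = None,
        constrained_nakagami: bool = True,
        glcm_levels: int = 16,
        aggregate: bool = True,
    ):
        self.spectral_config = spectral_config
        self.hk_lookup = hk_lookup
        self.hk_lookup_kwargs = hk_lookup_kwargs
        self.constrained_nakagami = constrained_nakagami
        self.glcm_levels = glcm_levels
        self.aggregate = aggregate

    def fit(self, X=None, y=None):
        self.spectral_config_ = self.spectral_config or SpectralConfig()
        if self.hk_lookup is not None:
            self.hk_lookup_ = self.hk_lookup
        else:
            logger.info("building homodyned-K lookup table")
            self.hk_lookup_ = build_hk_lookup(**(self.hk_lookup_kwargs or {}))
        return self

    def transform(self, lesions: list[LesionRecord]) -> pd.DataFrame:
        if not hasattr(self, "hk_lookup_"):
            self.fit()
        rows = []
        failed: list[str] = []
        for rec in lesions:
            lesion_rows = []
            try:
                for frame, mask in rec.scans:
                    feats = extract_scan_features(
                        frame,
                        mask,
                        self.spectral_config_,
                        self.hk_lookup_,
                        constrained_nakagami=self.constrained_nakagami,
                        glcm_levels=self.glcm_levels,
                    )
                    feats["lesion_id"] = rec.lesion_id
                    feats["scan_label"] = frame.scan_label
                    feats[LABEL_COLUMN] = rec.label
                    lesion_rows.append(feats)
            except (ValueError, RuntimeError) as err:
                failed.append(rec.lesion_id)
                warnings.warn(
                    f"lesion {rec.lesion_id!r} withheld from the feature table "
                    f"(scan {frame.scan_label!r}: {err})",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            rows.extend(lesion_rows)
        if not rows:
            raise FeatureExtractionError(
                f"no lesion survived extraction; failures: {failed}"
            )
        table = pd.DataFrame(rows)
        table = canonicalize_feature_table(table, finalized=False)
        # alpha is undefined (NaN) for post-Rayleigh envelopes; a finalized
        # table cannot carry NaN, so flag and withhold those lesions too
        bad = table[FEATURE_COLUMNS].isna().any(axis=1)
        if bad.any():
            dropped = sorted(table.loc[bad, "lesion_id"].unique())
            warnings.warn(
                f"lesions with undefined features withheld: {dropped}",
                UserWarning,
                stacklevel=2,
            )
            table = table[~table["lesion_id"].isin(dropped)]
        if self.aggregate:
            table = aggregate_scans(table)
        return canonicalize_feature_table(table.reset_index(drop=True))


def extract_all_features(
    lesions: list[LesionRecord],
    spectral_config: SpectralConfig | None = None,
    hk_lookup: HKLookupTable | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper over :class:`QUSFeatureExtractor`."""
    return (
        QUSFeatureExtractor(
            spectral_config=spectral_config, hk_lookup=hk_lookup, **kwargs
        )
        .fit()
        .transform(lesions)
    )
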