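# qustc — intratumoral quantitative-ultrasound lesion characterization

`qustc` implements a breast-lesion classification pipeline built on the three
major families of quantitative-ultrasound (QUS) descriptors that can be
extracted from raw radiofrequency (RF) echo data:

* **spectral features** — a Hamming window (2.4 mm, 87.5 % overlap) slides
  down each RF line; the windowed power spectrum in dB is fitted over its
  −6 dB band with the line `P(f) = I + s f`, giving parametric images of the
  spectral slope `s` (dB/MHz), intercept `I` (dB) and midband fit
  `M = I + s f₀` (dB at the band center `f₀`).  Frequency-dependent
  attenuation is compensated with `s′ = s + 2αd` (α in dB/MHz-cm, `d` the
  one-way window depth in cm; the intercept is attenuation-invariant).
  Intratumoral mean and standard deviation of the three images give six
  features;
* **envelope statistics** — all intratumoral samples of the echo envelope
  (analytic-signal magnitude) are fitted with the Nakagami distribution
  (moment estimators `Ω = E[R²]`, `m = Ω²/var(R²)`, constrained `m ≥ 0.5`,
  and the derived scatterer cross-section `α = ½√(Ω(1−m)/(2m))`) and with
  the homodyned-K distribution (coherent-to-diffuse ratio `k`, effective
  scatterer number `μ`, and `h = 1/(k+1)`), the latter via level-curve
  matching of the SNR, skewness and kurtosis of fractional-order amplitude
  moments (orders 0.72 and 0.88) against a Monte-Carlo lookup table;
* **texture** — the envelope crop over the tumor's minimum bounding
  rectangle is quantized to 16 gray levels and gray-level co-occurrence
  matrices at distances 1–5 px and angles 0°/45°/90°/135° yield contrast,
  correlation, energy and homogeneity, averaged over the 20 settings.

The 16 descriptors per lesion (multi-scan values averaged) feed a
classification study: Wilcoxon rank-sum screening, hybrid SMOTE–Tomek
resampling for imbalanced cohorts, sequential forward selection (SFS) with a
cross-validated misclassification criterion, and evaluation of Mahalanobis
5-NN, linear SVM and random-forest classifiers under stratified holdout,
10-fold CV and leave-one-out schemes (accuracy / sensitivity / specificity /
AUC with bootstrap CIs).

A synthetic-RF module simulates linear-array acquisitions from random
scatterer fields with controllable scatterer density, coherent scattering
and attenuation, so the whole pipeline is testable with known ground truth.

## Worked example

```python
import numpy as np
from qustc import (
    SimConfig, simulate_lesion_dataset, QUSFeatureExtractor,
    smote_tomek, cross_validate, MahalanobisKNN,
    FEATURE_COLUMNS,
)

# a small two-class cohort of simulated RF lesions, two scans each
lesions = simulate_lesion_dataset(6, 6, scans_per_lesion=2,
                                  base_config=SimConfig(n_lines=96, n_samples=700),
                                  seed=0)
extractor = QUSFeatureExtractor(
    hk_lookup_kwargs=dict(n_k=16, n_mu=16, mc_samples=100_000, seed=0)
).fit()
table = extractor.transform(lesions)
print(table[["lesion_id", "nakagami_m", "hk_k", "label"]].head(3))
```

```
    lesion_id  nakagami_m   hk_k  label
0  sim-b-0000         0.5  0.405      0
1  sim-b-0001         0.5  0.385      0
2  sim-b-0002         0.5  0.385      0
```

Each row is one lesion: `nakagami_m` is the constrained Nakagami shape
(0.5 = strongly pre-Rayleigh scattering, typical of sparse scatterer
fields), `hk_k` the homodyned-K coherent-to-diffuse ratio, and `label` the
class (1 = malignant).  On an imbalanced feature table the resampling +
evaluation stage looks like:

```python
from qustc import simulate_feature_table, SMOTETomek
table = simulate_feature_table(104, 26, seed=0)     # 4:1 benign:malignant
X, y = table[FEATURE_COLUMNS].to_numpy(), table["label"].to_numpy()
report = cross_validate(X, y, MahalanobisKNN(), scheme="kfold",
                        resampler=SMOTETomek(random_state=0), seed=0)
print(f"sensitivity {report.sensitivity:.1f}%  specificity "
      f"{report.specificity:.1f}%  AUC {report.auc:.3f}")
```

```
sensitivity 87.4%  specificity 75.7%  AUC 0.904
```

Without the resampler the same classifier reaches only 42.3 % sensitivity
at 100 % specificity — the majority-class bias the hybrid resampler exists
to remove.

There is also a CLI (`qustc simulate / extract / screen / resample /
select / evaluate / run-study`); `qustc run-study config.yaml` drives the
whole flow from a YAML file and writes feature tables, screening tables,
SFS traces, evaluation reports and ROC curves to an output directory.

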