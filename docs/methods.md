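# Methods

## Signal model and scope

The package operates on raw RF echo frames: real matrices with rows indexed
by axial sample and columns by scan line, together with the sampling
frequency, transducer center frequency and an assumed sound speed (default
1540 m/s).  The axial sample spacing is `c/(2 fs)` (two-way travel).  The
echo is modeled as a superposition of scattered wavelets from sub-resolution
scatterers; system and diffraction effects are not modeled or compensated —
only frequency-dependent attenuation is.  Labels encode malignant as the
positive class (1) everywhere; sensitivity therefore always refers to
malignant detection.

## Spectral parameterization

A Hamming window of physical length 2.4 mm (125 samples at 40 MHz / 1540
m/s) slides down each line with 87.5 % overlap (hop `max(1,
round(N(1−overlap)))` = 16 samples).  Per window the power spectrum is the
Hamming-tapered periodogram in dB.  The usable band is determined once per
frame: the average linear-power spectrum over all windows and lines is
converted to dB and the contiguous interval within 6 dB of its peak is
taken (ties at the peak resolve to the lowest frequency; a band clipped at
the grid edge is flagged; fewer than 3 bins is an error).  Keeping the band
— and hence the band center `f₀` — fixed per frame makes the midband
identity `M = I + s f₀` hold with a single frame-level `f₀`.

Within the band, ordinary least squares of dB power on frequency gives the
slope `s` (dB/MHz) and intercept `I` (dB at 0 MHz).  Attenuation assumed
linear in frequency with coefficient α (default 1.0 dB/MHz-cm, an effective
soft-tissue value) is compensated by `s′ = s + 2αd` where `d` is the one-way
depth of the window center in cm measured from the first axial sample and
the factor 2 covers round-trip propagation; the midband is recomputed from
the compensated slope and the unchanged intercept (the intercept is
attenuation-invariant under a linear-in-f model).  A `subtract` correction
mode applies the term with the opposite sign, for replicating pipelines
that state the correction as `s − 2αd`; physical compensation is the
default.  Spectra are computed per
line with no lateral averaging and no reference-phantom normalization; a
hook for reference-spectrum subtraction exists but defaults off.

Intratumoral means and standard deviations (sample sd, n−1; a single-pixel
region is assigned sd 0 with a warning) of the midband/intercept/slope
images give the six spectral features.  The radiologist ROI is drawn on the
RF grid; a parametric pixel is considered intratumoral when the RF-grid mask
is true at that window's center sample on the same line (nearest-window
rule, no dilation or erosion).

## Envelope statistics

The envelope is the magnitude of the per-line analytic signal.  Both
distribution fits use *all* intratumoral envelope samples at once
(whole-tumor fitting) rather than sub-windows: this pools the largest
sample for stable estimation at the cost of ignoring within-tumor
attenuation, which is the methodological trade-off the pipeline adopts
deliberately.

**Nakagami.**  `Ω = E[R²]` and `m = Ω²/var(R²)` with population (n)
denominators — these are moment estimators, not descriptive statistics, and
the package deliberately distinguishes the two denominators (descriptive
ROI statistics use n−1).  In constrained mode `m` is clipped up to 0.5 with
a flag, the standard Nakagami-parameter bound, applied post hoc since the
moment estimate itself is unconstrained.  Via the K-distribution
correspondence `M = 2m/(1−m)`, `b = 2√(2m/(Ω(1−m)))`, the derived effective
scatterer cross-section is `α = 1/b = ½√(Ω(1−m)/(2m))`, defined only for
0 < m < 1 and reported as NaN (flagged) otherwise.  The estimator is scale
equivariant: scaling amplitudes by c leaves m unchanged and scales Ω by c².

**Homodyned K.**  The model is parameterized by the coherent-to-diffuse
amplitude ratio `k = s/σ`, the effective scatterer number per resolution
cell `μ`, and the derived diffuse-to-total power ratio `h = 1/(k+1)` (an
exact identity, enforced to machine precision).  σ² denotes the *total*
diffuse power; with that convention the density's Bessel-integral kernel is
`[1 + x²σ²/(4μ)]^(−μ)` (conventions defining σ² per quadrature component
write 2μ), which the package's quadrature oracles use and which is verified
against the closed-form K distribution at k = 0.

Estimation follows the fractional-moment approach: the SNR (mean over
population sd), skewness and raw kurtosis of `A^ν` for ν ∈ {0.72, 0.88} —
six scale-invariant statistics — are matched against Monte-Carlo level
curves tabulated on a grid of k ∈ [0, 3] (61 linear nodes) × μ ∈ [0.01,
1000] (101 log-spaced nodes), each node estimated from 300 000 draws of the
compound sampler at unit diffuse power.  The orders follow the established
fractional-moment estimator lineage and are configurable.  Two estimator-
engineering choices matter for accuracy near the weakly identified region
(k near 0 at moderate-to-large μ, where the level curves are locally flat
in k):

* the table is built with *common random numbers* — one set of base draws
  serves every node, the gamma mixing variable obtained from shared
  uniforms through the inverse CDF — so the Monte-Carlo noise of the level
  curves is a smooth correlated surface and the node-to-node differences
  that locate the objective minimum are nearly noise-free;
* the matching objective is a minimum-chi-square style sum: each statistic's
  squared deviation is weighted by the inverse of its bootstrap sampling
  variance (32 fixed-seed replicates on the input sample).  The SNR is two
  orders of magnitude more precise than the kurtosis and carries most of
  the identifying information; equal-weight relative deviations would let
  kurtosis noise dominate.

The winning node is refined by bilinear interpolation of the tabulated
statistics (linear in k, linear in log μ) on its 3×3 neighborhood,
minimizing the same objective on a 41×41 sub-grid.  The build takes a few
minutes once and is cached to HDF5 keyed by a parameter fingerprint.  The
grid floor μ = 0.01 and ceiling 1000 are package choices covering the
clinically reported range (μ well below 1 in breast tissue) with margin.

The sampler draws `A = |kσ + g·(z₁+iz₂)/√2|` with `g² ~ Gamma(shape μ, mean
σ²)` and standard-normal z; it is validated against numerical quadrature of
the density (piecewise integration between Bessel zeros) by KS distance,
and cross-checked against the Nakagami sampler at matched first two
intensity moments (k = 0, μ = 2m/(1−m)).

## Texture

Texture is computed on the linear envelope magnitude (log compression
available as an option) over the tumor's minimum bounding rectangle —
pixels inside the rectangle but outside the mask are included, matching the
rectangle-based protocol.  The crop is linearly quantized to 16 levels over
its own range (`level = 1 + floor((v−min)·L/(max−min))`, clipped; a
constant crop maps to level 1 with a degeneracy flag).  Directed
co-occurrence matrices are accumulated at distances 1–5 px and angles
0°/45°/90°/135° (offsets (0,+d), (−d,+d), (−d,0), (−d,−d) with rows growing
downward), normalized to probabilities; a symmetric mode is available but
off by default since the four listed angles are directed.  Contrast
`Σ(i−j)²P`, correlation `Σ(i−μᵢ)(j−μⱼ)P/(σᵢσⱼ)`, energy `ΣP²` and
homogeneity `ΣP/(1+|i−j|)` are computed per matrix — the homogeneity
denominator uses |i−j| so the weight is symmetric and positive — and each
feature is averaged over the 20 settings.  Correlation is undefined when a
marginal sd is zero; undefined values are excluded from the average with a
flag, and all-undefined (constant crop) is an error.  The bounding box must
exceed 6×6 px (the largest offset plus one).

## Resampling

Neighbor searches (SMOTE neighbors and Tomek links) use Euclidean distance
on z-scored features, because the 16 descriptors span several orders of
magnitude and an unscaled metric would be dominated by Ω; synthetic samples
are constructed in the original feature space.  SMOTE cycles the minority
samples round-robin so the synthetic count spreads evenly, picks one of the
T = 5 nearest minority neighbors uniformly, and interpolates at
Uniform[0,1]; T is reduced with a warning if the minority has fewer than
T+1 members.  Tomek links are strict mutual-nearest-neighbor opposite-class
pairs; the undersampler removes the majority member of each link.

The hybrid default is Tomek-first: remove majority members of links, then
SMOTE the minority up to the reduced majority count, leaving exact balance
(104/26 → 93/93 when 11 links are found).  The alternative order (SMOTE
first, Tomek as post-hoc cleaning) is exposed via `order="smote_first"`;
only the Tomek-first order reproduces the balanced counts the default is
designed around.  Resampling an entire dataset before cross-validation
leaks synthetic points into test folds; that mode
(`leakage_mode="dataset"`, the default, as commonly practiced in applied
studies) therefore logs a warning, and a leakage-safe mode resampling
inside each training fold only is available.

## Selection and evaluation

Sequential forward selection wraps any classifier: candidates are scored by
10-fold stratified-CV misclassification (folds shuffled with a fixed seed so
all subsets are compared on identical folds; folds reduced to the smaller
class count when necessary), a candidate is accepted only on a strict
improvement, ties break toward the lower feature index, and the search
stops at the first non-improving round — so the accepted criterion sequence
is strictly decreasing by construction.

The classifier roster: 5-NN under the Mahalanobis metric with the inverse
covariance estimated from the training features (ridge-loaded if
ill-conditioned; K must be odd so votes cannot tie), a linear SVM (C = 1 on
standardized inputs), and a 100-tree random forest with √p features per
split and a fixed seed.  Scores are oriented so larger means malignant
(vote fraction / signed margin / tree fraction) and hard labels use each
model's natural threshold.

Validation schemes: stratified 60/40 holdout (metrics on the held-out 40 %),
stratified 10-fold CV and LOOCV.  Out-of-fold scores are pooled and a
single ROC/AUC and confusion matrix computed on the pooled predictions
(micro-averaging) rather than averaging per-fold metrics; this is a
documented choice and the per-report seed and scheme are recorded.  The AUC
95 % CI is a seeded stratified bootstrap with 2000 replicates (percentile
method); the bootstrap count is configurable and tests use fewer replicates
for speed.  The rank-sum screen uses the two-sided Wilcoxon rank-sum test —
exact enumeration when the pooled group size is ≤ 12 and tie-free, normal
approximation with tie correction otherwise — with tiers `~` (p ≥ 0.05),
`*` (p < 0.05), `**` (p < 0.001).

## Synthetic RF generator

Each scan line convolves a Gaussian-modulated cosine pulse (default 10 MHz,
60 % fractional bandwidth at −6 dB) with a sparse reflectivity train:
per-sample Poisson scatterer counts with standard-normal amplitudes, drawn
at a density set per resolution cell, where the resolution cell is the
pulse's −6 dB envelope length.  Because counts are Poisson and the pulse
weights scatterers unevenly, the configured density is an *effective*
target for μ, not an exact one.  An optional coherent component adds
constant-amplitude scatterers spaced one resolution cell apart inside the
lesion with amplitude k times the per-cell diffuse RMS.  Attenuation is
applied as a depth-varying frequency-domain gain `10^(−2αfd/20)` via
half-overlapping 128-sample Hann blocks (overlap-add); 128 samples keeps
the depth quantization fine enough that the induced spectral-slope depth
trend reproduces −2α within sampling noise.  The lesion is an ellipse
(default semi-axes 30 % of each dimension) with its own scatterer
statistics; simulated benign lesions default to sparser, less coherent
scattering than malignant ones, which drives the class contrast of the
end-to-end study path.

Default frames are 512 lines × 2600 samples at 40 MHz (≈5 cm); tests and
the study smoke paths use smaller frames (e.g. 96×700) purely as a problem
size, with the same physics.

What the generator does *not* emulate: diffraction/beamforming, speckle
correlation across lines (lines are independent), electronic noise, TGC,
and tissue heterogeneity beyond the single elliptical lesion.  Passing
end-to-end tests therefore demonstrates correctness of the estimators under
the stated scattering model, not clinical performance.

The feature-table simulator is a separate, purely statistical generator: it
draws independent truncated normals per class with default means/sds chosen
to mimic realistic benign/malignant separation of the 16 descriptors
(including the characteristic strong separation of the envelope-statistics
features), and supports arbitrary imbalance (the 4:1 case is the reference
configuration).  It intentionally ignores inter-feature correlation, so
multivariate classifier accuracies on these tables are optimistic relative
to real data; the tables are meant for testing resampling/selection/
evaluation machinery, not for performance claims.

## Numerical notes and degenerate inputs

* Zero-power spectral bins are floored at a configurable dB floor (default
  −120 dB) with a flag; synthetic validation studies lower the floor to
  −300 dB to avoid clipping deeply attenuated windows.
* The attenuation-correction equivalence test uses a margin of 0.15
  dB/MHz/cm rather than a pure CI-contains-zero test: finite-window
  spectral smoothing (the Hamming main lobe widening the measured Gaussian
  spectrum while the attenuation downshift is governed by the true
  spectrum) leaves a ~1–2 % residual of the induced trend that a
  sufficiently powered significance test would detect despite being
  practically irrelevant.
* Nakagami fitting requires ≥ 10 strictly positive samples with nonzero
  intensity variance; homodyned-K fitting requires ≥ 100 samples with
  spread in every fractional moment.
* A lesion whose scan fails any extraction stage (e.g. an ROI too small for
  texture or not covering a window center) is withheld from the finalized
  feature table with a warning naming the lesion, as is any lesion with an
  undefined derived feature (α at m ≥ 1); finalized tables carry no NaN.
* All stochastic stages take explicit seeds; fixed seeds give bit-identical
  samplers, lookup tables, resampling output and study artifacts.

## Known limitations

* The homodyned-K estimator's accuracy is grid- and Monte-Carlo-limited;
  k is weakly identified near k = 0 for large μ (flat level curves).  At
  the Rayleigh limit proper (k = 0, μ → ∞) k is *not* identifiable on a
  finite μ grid: the SNR-versus-k curve at the μ ceiling is non-monotone
  and its minimum coincides with the Rayleigh value, so fully developed
  speckle maps to the μ ceiling with a small compensating k (≈0.2–0.3 at a
  ceiling of 10³) no matter how large the sample.  The fitted distribution
  is still Rayleigh to a fraction of a percent; only the (k, μ)
  coordinates along the ridge are degenerate.  Clinically reported breast
  values (k ≈ 0.3–0.9, μ < 1) are far from this region.
* Whole-tumor envelope fitting mixes depths; with attenuation present the
  fitted m is biased low relative to a windowed protocol — visible in the
  simulator, where attenuated frames yield constrained fits at the 0.5
  bound.
* Ω and the derived cross-section α are dataset-scale-dependent (raw
  amplitude units); only scale-invariant parameters (m, k, h, μ) are
  comparable across acquisitions.
* The holdout/CV machinery assumes binary labels throughout.
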