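# Methods

This note documents the models, conventions and design choices behind
`serumftir`, in the spirit of the methods appendices that accompany
statistical packages: what each stage computes, which knobs matter, what
the synthetic benchmark does and does not establish.

## Data model and conventions

A `SpectrumSet` holds a strictly ascending wavenumber grid (cm⁻¹) and an
absorbance matrix with one row per sample. All window arithmetic uses
closed intervals [lo, hi]; windows are sorted and merged on construction
so the union is canonical. Class labels are normalized internally to
{0 = No-Stop, 1 = Start&Stop}; Start&Stop (the transient-dysfunction
trajectory) is the positive class in every metric. Wide CSV (samples as
rows, numeric wavenumber headers) is the canonical exchange format; the
JCAMP-DX reader is a single-spectrum convenience covering the
`(X++(Y..Y))` and `XYPOINTS` forms with XFACTOR/YFACTOR scaling.

Two window configurations ship as constants: 600–1900 + 2800–3400 cm⁻¹
(fingerprint/amide plus C–H stretch; the default) and the reduced
600–900 + 2800–3400 cm⁻¹. The default pipeline uses the full
configuration because the synthetic benchmark plants class effects in the
carbohydrate (946–1161 cm⁻¹) and amide III (~1300 cm⁻¹) regions, which
the reduced fingerprint window would exclude.

## Quality control

Four per-spectrum metrics, computed jointly and never used to auto-drop
samples (post-hoc exclusion optimizes the very statistic one later
reports):

* **Amide I SNR** — maximum of the rubber-band-corrected signal in
  1600–1700 cm⁻¹ over the SD of residuals after linear detrending in
  1800–1900 cm⁻¹ (fallback 2000–2200 cm⁻¹ when degenerate, i.e.
  SD < 1e−12; both degenerate → +inf sentinel with a flag). Baseline
  handling of the numerator uses the package's canonical rubber-band
  correction; detrending the denominator prevents baseline slope from
  masquerading as noise.
* **Spike burden** — first difference of the 900–1800 cm⁻¹ values,
  z-scored with 1.4826·MAD (Gaussian-consistent); |z| > 6 flags a
  difference, and runs of consecutive flagged differences merge into one
  event, so a single-point spike (two adjacent large differences) counts
  once. Zero MAD (e.g. a perfect ramp) returns 0 events with a
  `degenerate-mad` flag. Note that sharp genuine absorption edges can
  register as events when the noise floor is very low; the metric is a
  relative screen, not an absolute artifact count.
* **Spectral coherence** — spectra are window-restricted (900–1800 cm⁻¹)
  and unit-normalized *first*; the reference is the pointwise median of
  the normalized spectra. Normalizing before taking the median makes the
  metric exactly invariant to per-spectrum multiplicative gain
  (film-thickness variation), which is the artifact it should ignore.
  The flag threshold (default cosine < 0.99) is configurable.
* **Baseline fraction** — trapezoidal area of the rubber-band baseline
  over the area of the raw signal in the fingerprint window, in percent.
  Bounded in [0, 100] for nonnegative spectra; with noisy near-zero
  signal it can dip marginally negative.

Joint flagging adds a cross-sample robust-z screen (|z| > 3.5 on any
metric, MAD-based). On clean synthetic cohorts this occasionally flags a
mild relative outlier — expected behavior for a report-only screen with
a tight cohort distribution.

## Preprocessing

* **Rubber-band baseline** = lower convex hull of the (wavenumber,
  absorbance) points (monotone-chain construction), linearly interpolated
  between hull vertices. The corrected spectrum is nonnegative and
  exactly zero at hull vertices including both endpoints. No iterative
  "suction" variant is implemented; the hull definition is deterministic
  and oracle-checkable.
* **Vector normalization** = scaling each row to unit Euclidean norm,
  over whatever axis is current (window-restricted when it follows
  restriction). Euclidean ("unit vector") normalization is used
  throughout; SNV is not implemented.
* **Savitzky–Golay derivatives** — polynomial order 2, 15-point window by
  default, derivative order 0/1/2, scaled by the grid spacing so
  derivatives are per (cm⁻¹)^d. Edges keep the terminal polynomial fits
  (scipy `mode="interp"`), so output length equals input length and
  feature indices stay aligned with wavenumbers. When window restriction
  creates gaps (e.g. 1900→2800 cm⁻¹), the filter runs per contiguous
  segment and never across a gap — smoothing across a spectral gap is
  physically meaningless.
* **Atmospheric masking** replaces the CO₂ (2300–2400 cm⁻¹) and
  water-vapor (1790–1960 cm⁻¹) regions by linear interpolation between
  region-edge values. This is a region-excision stand-in, not a
  spectral-library vapor subtraction.

Steps compose in declared order; the window stage (before/after steps) is
explicit in the config and recorded in a provenance string. Nine named
variants cover the sensitivity grid: raw, 1st/2nd derivative each ± vector
normalization, rubber-band ± vector normalization, vector normalization
alone, and atmospheric masking (whose windows necessarily apply after the
mask, since the mask regions lie in the excluded gap).

## Unsupervised diagnostics

Cosine distance d = 1 − cos ∈ [0, 2] on the preprocessed matrix.
"Ward-type" clustering applies the Lance–Williams Ward update recursively
to the squared input distances, with deterministic smallest-index
tie-breaking; Ward's Euclidean assumption is knowingly violated for
cosine distances, so the dendrogram is a similarity diagnostic, not a
variance decomposition (heights are reported on the unsquared scale and
match scipy's Ward linkage on Euclidean inputs). Classical (Torgerson)
MDS double-centers the squared distances and eigendecomposes; negative
eigenvalues — possible for non-Euclidean inputs — are clipped with a
warning. t-SNE is treated as visualization plumbing (scikit-learn, exact
method, seeded, cosine metric) and is asserted only for determinism and
coarse class separation.

None of these functions accept labels; the pipeline hands them label-free
views, enforcing structurally that nothing before the supervised stage
can see class membership.

## Supervised modeling

Continuous spectral features are discretized per feature by
equal-frequency cuts (quantiles of the *training* data, numpy midpoint
convention; duplicate cuts collapse bins; intervals are half-open,
right-closed at +∞). Four bins by default — a robust choice at 23
training samples per fold, giving ~6 samples per bin.

Symmetric uncertainty SU(X;Y) = 2·I(X;Y)/(H(X)+H(Y)) uses plug-in
entropies in bits and is defined as 0 when both variables are constant.
FCBF keeps features with SU(f, label) > δ (δ = 0 by default: any positive
association enters the predominance scan), orders them by label SU (ties
by index), and removes any feature f for which a retained higher-ranked g
has SU(f, g) ≥ SU(f, label). Top-k univariate ranking is available as an
alternative selector.

The classifier is Gaussian Naïve Bayes on the *continuous* values of the
selected features: per class/feature Gaussians (MLE variance floored at
1e−9 × the largest pooled feature variance), empirical class priors,
posteriors via log-sum-exp. Discretization exists only to make the
information-theoretic selection well-defined.

**Leakage control.** Preprocessing steps are per-sample transforms with
no cross-sample fitting, so they are applied once. Everything that learns
from data — cuts, SU ranking, FCBF pruning, NB parameters — is refitted
on the n−1 training samples of each leave-one-out fold; the held-out
sample is transformed with training-fitted cuts and scored by the
training-fitted model. Aggregate metrics are computed once on the n
out-of-fold scores; resubstitution (train-on-all/predict-all) metrics are
recorded separately as the optimistic reference. An `feature_subset`
escape hatch exists solely so the tests can demonstrate how much
full-data selection inflates apparent AUC (≈ +0.3 at n = 24 on pure-noise
cohorts).

AUC is the Mann–Whitney rank statistic with midrank ties; confusion
metrics use a fixed 0.5 threshold (balanced design), with per-class and
macro-averaged F1/precision/recall and specificity = recall of the
negative class. The permutation test shuffles labels (preserving class
counts) and reruns the entire nested pipeline per permutation — 10
permutations by default — recording both LOOCV and resubstitution AUC.
The reliability table bins out-of-fold probabilities by quantiles
(5 bins by default, ≈ 5 predictions per bin at n = 24; ties collapse
bins) and the Brier score is the mean squared probability error. Under
1:1 matched case-control sampling these probabilities are internal
discriminative scores, not population risks; the table carries that
caveat.

The discriminant-band report aggregates per-fold selections: selection
frequency per wavenumber, contiguous selected wavenumbers (gap ≤ 2 grid
steps) merged into bands with min–max bounds, ranked by mean label-SU.

## Synthetic cohorts

The generator emulates a balanced 24-sample (12 vs 12) dried-serum FTIR
cohort on a 400–4000 cm⁻¹ grid at 2 cm⁻¹ spacing. Clean spectra are sums
of Gaussian bands (amide A/I/II/III, COO⁻, carbohydrate C–O/phosphate,
CH₂/CH₃ stretches; amide I amplitude ≈ 1 as the reference scale).
Gaussian rather than Voigt shapes are used deliberately: band-shape
realism is irrelevant to pipeline correctness, and Gaussian derivatives
are analytic, which keeps oracles simple. The class effect is an additive
amplitude shift on four bands planted inside the discriminant regions
this assay reports (1045, 1300, 2880, 3100 cm⁻¹), scaled by a single
`effect_scale` knob.

Corruption layers mirror the artifact classes the QC stage screens for:
multiplicative gain in [0.85, 1.15] (film thickness), a convex degree-2
polynomial baseline with nonnegative curvature plus linear tilt (exactly
the family rubber-band correction removes, making end-to-end tests
sharp), white noise (SD 0.004 ≈ 0.4 % of amide I), and Poisson-count
single-grid-point spikes (mean 2 per spectrum, amplitude 0.05–0.5,
random sign). Default effect sizes are set so the benchmark spans the
dynamic range of interest: `effect_scale` 0 gives chance-level nested
LOOCV AUC and the default 1.0 gives AUC ≥ 0.9 under the default
pipeline, so both the null calibration and the power behavior of the
analysis are observable.

All randomness flows through one seeded numpy PCG64 generator named in
the sidecar; the sidecar records the full truth configuration and every
per-sample draw (gain, baseline coefficients, spike positions and
amplitudes), so any cohort regenerates bit-identically from the sidecar
alone.

**What the benchmark does not show.** The generator has no Mie/EMSC
scattering, no water-vapor rotational fine structure, no correlated
biochemical covariation between bands, and its class effect is a clean
additive shift rather than the distributed, correlated perturbations real
serum shows. Passing tests therefore establish that the *pipeline* is
correct and honest (calibrated under the null, powerful under a planted
signal, leak-free), not that any particular clinical discrimination is
real or that the published clinical performance is reproduced —
reproducing those numbers would require the private clinical spectra.

## Numerical choices and degenerate inputs

* Hull arithmetic uses exact float comparisons with a final clamp of
  negative "float dust" in the corrected spectrum; corrected values at
  hull vertices are exactly 0.
* Window restriction returns contiguous arrays so downstream reductions
  are layout-independent and reruns are bit-identical.
* Non-uniform grids are rejected by the SG filter with instructions to
  restrict per contiguous segment; segments shorter than the filter
  window raise rather than silently shrink the window.
* Zero-norm rows, one-class training folds, empty window intersections,
  constant features and zero-MAD differences all raise or flag
  explicitly rather than producing NaNs.
* Nested LOOCV on null data runs slightly *below* AUC 0.5 on average
  (≈ 0.45–0.49 depending on the seed set): with selection and priors
  refitted on each fold, the held-out sample's own class is
  under-represented in training — a known pessimistic bias of
  leave-one-out at small n, visible here because the benchmark measures
  it directly.

## Problem sizes

The test suite and the acceptance script use the study-scale design
throughout (n = 24, 12 vs 12, 1801-point grid): 50 cohorts for null
calibration and the leaky-selection contrast, 20 for planted-band
recovery and the variant ordering, 10 label permutations, 20 seeds per
point of the effect-size monotonicity sweep. The full suite runs in
about a minute on one CPU.
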