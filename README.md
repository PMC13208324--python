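# serumftir

Chemometric analysis of dried-serum FTIR spectra for small matched
case-control cohorts, built around the question of whether a pre-treatment
serum spectrum carries a multivariate biochemical signature of a later
clinical trajectory (here: transient pancreas-graft dysfunction —
"Start&Stop" — after simultaneous pancreas-kidney transplantation, 12
cases vs 12 matched controls).

The package provides the full analysis chain as a tested library:

* **Spectral I/O** — wide CSV/TSV matrices (samples × wavenumbers) and a
  minimal JCAMP-DX reader; strict ascending-grid conventions and
  closed-interval window restriction.
* **Quality control** — four per-spectrum metrics interpreted jointly:
  amide I SNR (rubber-band-corrected peak over detrended noise SD),
  MAD-based spike-event count on the first difference (|z| > 6),
  cosine similarity to the cohort median profile, and the baseline-area
  fraction. Flags are report-only; no sample is ever auto-excluded.
* **Preprocessing** — rubber-band baseline (lower convex hull), unit
  vector normalization, Savitzky–Golay derivatives (order 2, 15-point
  window), atmospheric-region masking; composable in any order and
  available as the 9 named variants of the sensitivity grid.
* **Unsupervised diagnostics** — cosine distances, Ward-type hierarchical
  clustering (Lance–Williams updates on squared distances), classical
  MDS, and a seeded t-SNE embedding. All label-blind by construction.
* **Supervised core** — equal-frequency discretization, symmetric
  uncertainty SU(X;Y) = 2·I(X;Y)/(H(X)+H(Y)), FCBF feature selection
  (predominance pruning) or top-k ranking, and Gaussian Naïve Bayes,
  evaluated by leave-one-out cross-validation with *all* data-driven
  steps refitted inside each fold. Validity checks: label-permutation
  test, quantile-binned reliability + Brier score, and a discriminant
  wavenumber-band report.
* **Synthetic cohorts** — a generator producing labeled dried-serum-like
  spectra (Gaussian amide/carbohydrate/lipid bands, convex baseline
  drift, film-thickness gain, white noise, sparse spikes) with complete
  ground-truth sidecars, so every stage is testable end-to-end without
  any clinical data.

## Worked example

```sh
python examples/03_classify_loocv.py
```

generates a 24-sample synthetic cohort with planted class-effect bands
and runs the default pipeline (Savitzky–Golay 2nd derivative + vector
normalization on the 600–1900 + 2800–3400 cm⁻¹ windows, FCBF + Gaussian
NB under LOOCV):

```
LOOCV metrics (out-of-fold):
  auc          1.000
  accuracy     1.000
  f1           1.000
  ...
top discriminant bands (merged per-fold selections, by mean SU):
 low_cm1  high_cm1  n_points  selection_frequency  mean_su
  1296.0    1308.0         7             1.000000 0.566473
  2878.0    2888.0         6             1.000000 0.541688
  1034.0    1044.0         5             0.583333 0.470412
```

The out-of-fold AUC of 1.0 says every held-out case was ranked above
every held-out control by a model that never saw it; the band report
localizes the signal to the amide III (~1300 cm⁻¹), C–H stretch
(~2880 cm⁻¹) and carbohydrate (~1040 cm⁻¹) regions where the generator
planted it. `examples/04_permutation_validity.py` shows the complementary
negative control: under shuffled labels the same pipeline collapses to
LOOCV AUC ≈ 0.44 while resubstitution AUC stays ≈ 0.95.

A thin CLI mirrors the stages
(`serumftir simulate|qc|preprocess|structure|fit|permute|bands|grid|run`).

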