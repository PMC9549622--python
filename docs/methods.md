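# Methods

## Problem setting

`metabocv` implements a discriminative metabolomics workflow for binned
¹H NMR biofluid spectra from a two-group animal study: lesioned (DTH)
versus control rats sampled at days 12, 28 and 60, in serum (194 bins)
and CSF (122 bins). The question the workflow answers is not "does a
single model separate the groups" but "does the *ensemble* of
cross-validated models separate them better than chance", and, when it
does, *which bins* drive the separation and how those bins relate to
histological and neurofilament covariates.

## The classifier

Each ensemble member is a two-class OPLS-DA model: one predictive latent
component plus `m ≥ 0` orthogonal components fitted by the standard
O-PLS NIPALS recursion (predictive weights `w ∝ Xᵀy_c`, orthogonal
weights obtained by removing the `w`-projection from the X-loading and
deflating `X` by the orthogonal scores). Classes are coded 0/1 and a
sample is assigned the code-1 class when `ŷ = (x_defl·w)c + ȳ ≥ 0.5`.
With `m = 0` the model is exactly a one-component PLS1; the test suite
uses that identity as an algebraic oracle.

The number of orthogonal components is chosen per training set by
leave-one-out cross-validation: `m` grows from 0 while the LOO accuracy
gain exceeds `tol = 0.01` (one accuracy point), capped at `max_orth = 3`.
Both values are exposed as keyword arguments; small caps keep selection
stable on the ~14-sample training sets this design produces.

VIP scores are computed from the predictive weights only:
`VIP_j = √(p·w_j²/Σw_k²)`, so `mean(VIP²) = 1` exactly and VIP > 1 flags
above-average contribution. Orthogonal components are deliberately
excluded — they model class-*unrelated* variation and several VIP
flavours exist in the literature; the predictive-weights variant ties
the ranking directly to the discriminant direction. Ensemble-level VIP
is the per-bin mean VIP across every fitted model (one per fold per
repetition) of the defined-class ensemble, ranked descending with ties
broken by bin id.

## The validation engine

One repetition of the external cross-validation: (1) balance the two
groups by uniform subsampling of the larger one; (2) if in random-class
mode, permute the labels over the balanced samples (sizes preserved) —
permutation happens *after* balancing so the null sees exactly the data
the defined ensemble sees; (3) partition into `k` folds (`k` = smaller
group size), each fold pairing one sample of each class at random;
(4) per fold: fit column scaling on the training portion, select `m` by
internal LOO, fit, predict the held-out pair; (5) pool all `2k` held-out
predictions into one accuracy. The ensemble is the vector of `R`
repetition accuracies (default `R = 100`). Accuracy is pooled rather
than averaged per fold; with equal fold sizes the two are identical.

Leakage control: constant-sum normalization is per-sample and applied
once up front; column centring/uv-scaling parameters always come from
the training portion of the current fold. Each repetition draws from a
counter-derived child stream of the master seed (`SeedSequence([seed,
rep])`), so results are reproducible and order-independent.

The defined ensemble is compared to the random-class ensemble with a
two-sample two-sided Kolmogorov–Smirnov test (exact small-sample
distribution when both ensembles have ≤ 100 members, asymptotic
otherwise). A separation is "valid" when `p < 0.05` *and* the defined
mean exceeds the null mean. Mean accuracy divided by the 50% chance
level gives the fold-change-over-chance summary used to compare
timepoints.

Two calibration facts about this engine are worth knowing:

- Repetition accuracies live on the grid `j/(2k)`, so the two ensembles
  are heavily tied and the classical KS p-value is *conservative*
  (simulations on null cohorts give mean p ≈ 0.73 instead of 0.5). The
  validity flag therefore has type-I error well below its nominal 5%;
  p-values near the threshold should be read as conservative bounds.
- The *defined*-label ensemble mean on a cohort with no real effect is
  unbiased (grand mean 50%) but highly cohort-dependent (SD ≈ 15
  points): with 8 + 8 fixed labels in ~200 dimensions, chance
  separability of one particular labeling varies a lot. The
  *random*-label ensemble re-permutes every repetition and is tightly
  calibrated (mean 50% ± ~1 point at 200 repetitions); this is why the
  chance reference is built from permuted labels rather than from
  "defined labels on null data".

## The synthetic cohort generator

Real spectra for this design are not publicly deposited, so the
generator emulates the data's assumed structure; its defaults are the
study conditions end to end. Per cohort: baseline bin means are drawn
log-uniformly over two decades (heterogeneous metabolite abundances);
each intensity is `baseline_j · g_ij · exp(ε)` with
`ε ~ N(−s²/2, s²)`, `s = √ln(1+CV²)` — multiplicative log-normal noise
with unit mean and configurable CV (default 0.1). Lesioned animals have
5 marker bins reduced by a timepoint-dependent fraction (defaults
30%/15%/5% at days 12/28/60 — an early-peaking perturbation that decays
toward control levels). Naive animals are generated identically to
controls. Group sizes default to 8 per group per timepoint.

Covariates (IBA1/GFAP densities, MBP/NfH loss areas, serum/CSF NfL) are
linear readouts of each animal's standardized mean marker-bin
log-deviation `z`: `sign·r·z + √(1−r²)·η` mapped onto group-level means
and SDs, with `r = covariate_corr` (default −0.55) for the
inflammation/NfL covariates and `−r` for the loss areas; loss areas are
identically zero in unlesioned animals. Levels are clipped at zero,
with means/SDs chosen far enough from zero that clipping is rare.

What the generator does *not* emulate: inter-bin correlation structure
from shared metabolites, baseline drift/misalignment artifacts, blood
contamination of CSF, or covariate kinetics beyond fixed group means.
Passing tests therefore demonstrate the *machinery* (calibration,
leakage control, recovery of planted structure), not the biology of any
particular real dataset.

## Numerical choices and degenerate inputs

- Constant-sum normalization uses a row total of 1.0; any positive
  constant is equivalent up to scale. Zero-sum or negative rows are
  rejected by name.
- Column scaling defaults to unit variance (n−1 denominator), the
  convention of the standard OPLS-DA tooling; zero-variance columns keep
  a unit divisor with a warning so constant bins survive small folds.
- The O-PLS recursion rejects `n_orth` beyond the usable rank and
  degenerate predictive directions (‖Xᵀy_c‖ ≈ 0).
- Binning integrates the piecewise-linear interpolant exactly over each
  bin interval (partial trapezoids at the edges), making binning a
  linear operator; bins intersecting an exclusion window are dropped
  whole. Defaults: 0.04 ppm bins over [0.2, 10.0] ppm, water window
  [4.5, 5.0] ppm excluded.
- VIP rank ties break by ascending bin id, so ranks are always a
  permutation of 1..p.
- Two-way ANOVA is restricted to complete balanced layouts (Type I =
  Type III there); within-timepoint contrasts use the pooled residual
  variance with the Sidak exponent equal to the total number of
  contrasts. Tukey HSD uses the studentized-range distribution
  (Tukey–Kramer under unequal n, via `scipy.stats.tukey_hsd`).
- Correlation matrices use pairwise-complete observations (n ≥ 3
  enforced) and report unadjusted two-tailed p-values, matching common
  practice for small exploratory panels.

## Problem sizes in tests

The test-suite ensembles run at the study's native configuration
(194 bins, 8 animals/group, 100–200 repetitions) where the property
being checked demands it — chance calibration, ensemble structure,
power/marker recovery — and at reduced sizes (30–40 bins, 15–40
repetitions) for structural and end-to-end checks where dimensionality
is irrelevant. The KS-calibration study uses 200 independent null
cohorts with 20-repetition ensembles.

## Known limitations

- Two-class problems only; no multi-class OPLS-DA, O2-PLS or kernel
  variants.
- The KS comparison inherits the tie-induced conservativeness described
  above; a permutation test with randomized tie-breaking would be
  exactly calibrated but is not what this workflow's field convention
  reports.
- Under the default generator conditions the expected ensemble accuracy
  for a 30% reduction in 5 of 194 bins is ≈ 82–84%, not higher: with
  ~14 training samples the predictive direction carries substantial
  weight on noise bins (each picks up a spurious |r| ≈ n^{−1/2}
  correlation), which dilutes the margin. This is a property of the
  classifier at this n/p ratio, not of the implementation.
- No multiple-testing control across correlation matrices (deliberate:
  the panel is small and exploratory).
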