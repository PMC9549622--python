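# metabocv

Cross-validated discriminative analysis of binned ¹H NMR metabolomics
data: OPLS-DA classification validated by balanced k-fold external
cross-validation ensembles against random-class null ensembles, VIP-based
ranking of discriminatory bins, and a univariate layer of
control-normalized fold changes, ANOVA post hoc tests and covariate
correlation matrices.

The package targets the situation common in small-animal biomarker
studies — two groups (e.g. lesioned vs control rats), handfuls of animals
per timepoint, hundreds of spectral bins per sample — where a single
fitted classifier is meaningless because almost any labeling of 8 + 8
samples is partially separable in 200 dimensions. The unit of evidence
here is instead an **ensemble of held-out accuracies**: repeated cycles
of (1) balancing group sizes, (2) random partitioning into k class-paired
folds (k = smaller group size), (3) fitting an OPLS-DA model per training
set with leave-one-out internal selection of the orthogonal components,
and (4) pooling the held-out predictions into one accuracy. A separation
counts as valid only when this ensemble beats the ensemble obtained with
randomly permuted class labels (two-sample Kolmogorov–Smirnov test plus a
higher mean). Mean accuracy / 50% gives the fold change over chance used
to compare perturbation strength across timepoints.

The OPLS-DA model is the canonical two-class formulation: one predictive
component `t = Xw`, `w ∝ Xᵀy_c`, plus m orthogonal components obtained by
the O-PLS NIPALS recursion (`w_o = p − (wᵀp)w`, deflation `X ← X −
t_o p_oᵀ`), prediction `ŷ = (x_defl·w)c + ȳ`, threshold 0.5. Variable
importance is `VIP_j = √(p·w_j²/Σ_k w_k²)` from the predictive weights,
averaged per bin over every model in the ensemble.

Because raw spectra for this kind of study are rarely deposited, the
package ships a first-class synthetic cohort generator (log-uniform
baseline abundances, multiplicative log-normal noise, marker bins with a
timepoint-decaying group effect, covariates correlated with the
marker-bin deviation) used by the tests and the examples. See
`docs/methods.md` for the full model description and its limitations.

## Worked example

```sh
python examples/02_validate_ensembles.py
```

builds the default synthetic serum cohort (194 bins, 8 animals per group
per timepoint, a 30% reduction of 5 marker bins at day 12) and prints:

```
defined-class ensemble: mean 85.6% (SD 2.9), k=8, 100 repetitions
random-class ensemble:  mean 52.1% (SD 16.5)
KS D = 0.930, p = 5.04e-47
fold change over 50% chance = 1.712
valid separation: True
```

The defined-class ensemble's mean held-out accuracy (85.6%) sits far
above the permuted-label ensemble (52.1%, i.e. chance), the KS test
separates the two accuracy distributions decisively, and the day-12
perturbation amounts to a 1.71-fold improvement over guessing. Running
`examples/03_top_metabolites_vip.py` on the same cohort shows the five
planted marker bins occupying ensemble-VIP ranks 1–5 (VIP 2.6–2.9 vs ≈ 1
for background bins) and their control-normalized means climbing from
~0.71 at day 12 back to ~1.0 at day 60 — the planted early-peaking
perturbation, recovered end to end. `examples/01_simulate_cohort.py` and
`examples/04_univariate_correlations.py` demonstrate the generator and
the univariate/correlation layer.

The same workflow runs from the shell on any conforming CSV pair:

```sh
metabocv simulate --n-per-group 8 --seed 3 --out-prefix cohort
metabocv validate --matrix cohort_matrix.csv --meta cohort_metadata.csv \
    --timepoint 12 --reps 100 --seed 1 --out day12.json
metabocv run-all --matrix cohort_matrix.csv --meta cohort_metadata.csv \
    --covariates cohort_covariates.csv --out-dir results
```

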