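"""Univariate layer: control-normalized fold changes, ANOVA with post hoc
corrections, and Pearson correlation matrices.

Conventions mirror common practice in small-animal biomarker studies:
lesioned-animal values are expressed relative to the mean of the control
animals at the same timepoint (so 1.0 means "at control level"); group
comparisons use one-way ANOVA with Tukey HSD or two-way (treatment x
timepoint) ANOVA with Sidak-corrected within-timepoint comparisons; and
associations between metabolite levels and histology/NfL covariates are
summarized as a Pearson correlation matrix with unadjusted two-tailed
p-values at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectralDataset

ALPHA = 0.05


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------
# control-normalized fold change


def normalize_to_control(
    values_dth,
    timepoints_dth,
    values_control,
    timepoints_control,
) -> pd.DataFrame:
    """Divide each lesioned-animal value by its timepoint's control mean.

    Returns a DataFrame with columns ``timepoint``, ``value`` and
    ``fold_change``; a value equal to its timepoint control mean maps to
    exactly 1.0.  Timepoints without controls, or with a non-positive
    control mean, are rejected.
    """
    vd = np.asarray(values_dth, dtype=float)
    td = np.asarray(timepoints_dth)
    vc = np.asarray(values_control, dtype=float)
    tc = np.asarray(timepoints_control)
    if vd.shape != td.shape or vc.shape != tc.shape:
        raise StatsError("values and timepoints must align")
    control_means = {}
    for t in np.unique(td):
        sel = vc[tc == t]
        if sel.size == 0:
            raise StatsError(f"no control values at timepoint {t}")
        m = sel.mean()
        if m <= 0:
            raise StatsError(f"control mean at timepoint {t} is {m}; must be > 0")
        control_means[t] = m
    fc = np.array([v / control_means[t] for v, t in zip(vd, td)])
    return pd.DataFrame({"timepoint": td, "value": vd, "fold_change": fc})


# ---------------------------------------------------------------------
# one-way ANOVA + Tukey HSD


@dataclass
class OneWayAnovaResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group_a, group_b, diff, p_adj


def one_way_anova_tukey(groups: dict[str, np.ndarray]) -> OneWayAnovaResult:
    """Classical one-way ANOVA with all-pairs Tukey HSD post hoc tests.

    ``groups`` maps group names to 1-D value arrays (each n >= 2).  Tukey
    p-values come from the studentized-range distribution with pooled
    within-group variance (Tukey-Kramer for unequal n).
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise StatsError("need at least two groups")
    for g, a in zip(names, arrays):
        if a.ndim != 1 or len(a) < 2:
            raise StatsError(f"group {g!r} needs >= 2 observations")
    grand = np.concatenate(arrays)
    if np.allclose(grand.var(), 0):
        # all observations identical: no between- or within-group variation
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
        if np.isnan(f_stat):  # zero within-group variance
            f_stat, p = np.inf, 0.0
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "diff": arrays[i].mean() - arrays[j].mean(),
                "p_adj": float(hsd.pvalue[i, j]),
            }
        )
    return OneWayAnovaResult(float(f_stat), float(p), pd.DataFrame(rows))


# ---------------------------------------------------------------------
# two-way ANOVA + Sidak


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment, p_adj = 1 - (1 - p)^m."""
    if not 0.0 <= p <= 1.0:
        raise StatsError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise StatsError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


@dataclass
class TwoWayAnovaResult:
    anova_table: pd.DataFrame  # F and p for both mains and the interaction
    comparisons: pd.DataFrame  # per-timepoint treatment contrasts, Sidak-adjusted


def two_way_anova_sidak(
    values,
    treatment,
    timepoint,
) -> TwoWayAnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction, plus
    Sidak-corrected treatment comparisons within each timepoint.

    Only complete balanced layouts are accepted (every treatment x
    timepoint cell has the same n >= 2), where Type I and Type III sums
    of squares coincide.  Within-timepoint contrasts use the pooled
    residual variance; the Sidak exponent m is the total number of
    contrasts.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "A": np.asarray(treatment),
            "B": np.asarray(timepoint),
        }
    )
    cells = df.groupby(["A", "B"], observed=True).size()
    a_levels = sorted(df["A"].unique().tolist())
    b_levels = sorted(df["B"].unique().tolist())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise StatsError("both factors need >= 2 levels")
    if len(cells) != len(a_levels) * len(b_levels):
        raise StatsError("empty cells: only complete factorial layouts are supported")
    if cells.nunique() != 1 or cells.min() < 2:
        raise StatsError("unbalanced design: every cell must have the same n >= 2")

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("value ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    anova = pd.DataFrame(
        {
            "effect": ["treatment", "timepoint", "interaction"],
            "F": [table.loc["C(A)", "F"], table.loc["C(B)", "F"],
                  table.loc["C(A):C(B)", "F"]],
            "p": [table.loc["C(A)", "PR(>F)"], table.loc["C(B)", "PR(>F)"],
                  table.loc["C(A):C(B)", "PR(>F)"]],
        }
    )

    mse = model.mse_resid
    dof = model.df_resid
    contrasts = []
    for b in b_levels:
        for a1, a2 in itertools.combinations(a_levels, 2):
            g1 = df.loc[(df["A"] == a1) & (df["B"] == b), "value"]
            g2 = df.loc[(df["A"] == a2) & (df["B"] == b), "value"]
            se = np.sqrt(mse * (1.0 / len(g1) + 1.0 / len(g2)))
            tval = (g1.mean() - g2.mean()) / se
            p_raw = 2.0 * stats.t.sf(abs(tval), dof)
            contrasts.append(
                {"timepoint": b, "group_a": a1, "group_b": a2,
                 "diff": g1.mean() - g2.mean(), "t": tval, "p_raw": p_raw}
            )
    comp = pd.DataFrame(contrasts)
    m = len(comp)
    comp["p_adj"] = [sidak_adjust(p, m) for p in comp["p_raw"]]
    return TwoWayAnovaResult(anova, comp)


# ---------------------------------------------------------------------
# correlation matrix


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float = ALPHA

    @property
    def significant(self) -> pd.DataFrame:
        return (self.p < self.alpha) & self.r.notna()

    def to_dict(self) -> dict:
        return {
            "r": self.r.to_dict(),
            "p": self.p.to_dict(),
            "n": self.n.to_dict(),
            "alpha": self.alpha,
        }


def pearson_corr_matrix(table: pd.DataFrame, alpha: float = ALPHA) -> CorrelationMatrix:
    """All-pairs Pearson r with two-tailed p (t distribution, n-2 df).

    Pairs are computed on pairwise-complete rows (n >= 3 required);
    zero-variance variables yield NaN entries and a warning instead of an
    error.  The matrix is symmetric with a unit diagonal.
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    n = pd.DataFrame(
        np.full((len(cols), len(cols)), len(table), dtype=int), index=cols, columns=cols
    )
    np.fill_diagonal(p.values, 0.0)
    for i, j in itertools.combinations(range(len(cols)), 2):
        x = table[cols[i]].to_numpy(dtype=float)
        y = table[cols[j]].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n.iloc[i, j] = n.iloc[j, i] = len(x)
        if len(x) < 3:
            raise StatsError(
                f"pair ({cols[i]}, {cols[j]}) has only {len(x)} complete rows; need >= 3"
            )
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"zero-variance variable in pair ({cols[i]}, {cols[j]}); r undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            r.iloc[i, j] = r.iloc[j, i] = np.nan
            p.iloc[i, j] = p.iloc[j, i] = np.nan
            continue
        res = stats.pearsonr(x, y)
        r.iloc[i, j] = r.iloc[j, i] = res.statistic
        p.iloc[i, j] = p.iloc[j, i] = res.pvalue
    return CorrelationMatrix(r=r, p=p, n=n, alpha=alpha)


# ---------------------------------------------------------------------
# marker trajectory


@dataclass
class MarkerTrajectory:
    bin_id: str
    normalized_means: pd.Series  # fold change vs control mean, per timepoint
    anova: OneWayAnovaResult
    returns_toward_control: bool


def marker_trajectory(
    dataset: SpectralDataset, bin_id: str, group: str = "DTH", control: str = "control"
) -> MarkerTrajectory:
    """Control-normalized trajectory of one bin across timepoints.

    For each timepoint, lesioned-animal values of ``bin_id`` are divided
    by the control mean; a one-way ANOVA with Tukey post hoc tests then
    compares the normalized values across timepoints.  The
    ``returns_toward_control`` flag reports whether the final timepoint's
    normalized mean is closer to 1.0 than the first's.
    """
    if bin_id not in dataset.bin_ids:
        raise StatsError(f"bin {bin_id!r} not in dataset")
    meta = dataset.metadata
    col = dataset.intensities[bin_id]
    tps = sorted(meta["timepoint"].astype(int).unique().tolist())
    if len(tps) < 2:
        raise StatsError("marker trajectory needs >= 2 timepoints")
    dth_mask = meta["group"] == group
    ctl_mask = meta["group"] == control
    for t in tps:
        t_mask = meta["timepoint"].astype(int) == t
        if not (dth_mask & t_mask).any() or not (ctl_mask & t_mask).any():
            raise StatsError(f"timepoint {t} lacks {group} or {control} samples")
    fc = normalize_to_control(
        col[dth_mask].to_numpy(),
        meta.loc[dth_mask, "timepoint"].astype(int).to_numpy(),
        col[ctl_mask].to_numpy(),
        meta.loc[ctl_mask, "timepoint"].astype(int).to_numpy(),
    )
    groups = {str(t): fc.loc[fc["timepoint"] == t, "fold_change"].to_numpy() for t in tps}
    anova = one_way_anova_tukey(groups)
    means = fc.groupby("timepoint")["fold_change"].mean()
    toward = abs(means.loc[tps[-1]] - 1.0) <= abs(means.loc[tps[0]] - 1.0)
    return MarkerTrajectory(
        bin_id=bin_id,
        normalized_means=means,
        anova=anova,
        returns_toward_control=bool(toward),
    )
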