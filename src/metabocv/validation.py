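"""Balanced external cross-validation ensembles and their null comparison.

The unit of evidence for a group separation is not a single model but an
ensemble of predictive accuracies from repeated cycles of

    (1) balancing the two groups by subsampling the larger one,
    (2) randomly partitioning the balanced samples into k class-paired
        folds (k = size of the smaller group),
    (3) fitting an OPLS-DA model on each training portion, choosing the
        number of orthogonal components by internal leave-one-out CV, and
    (4) pooling the held-out predictions into one accuracy per repetition.

Running the identical machinery with class labels randomly permuted
("random-class mode") yields the chance-level null ensemble; a separation
is only considered valid when the defined-class ensemble is significantly
above its null by a two-sample Kolmogorov-Smirnov test and higher in
mean.  Mean accuracy divided by the 50% two-class chance level gives the
fold-change-over-chance summary used to compare perturbation strength
across timepoints.

Each repetition draws its random numbers from a counter-derived child
stream of the master seed, so results are reproducible and independent of
execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectralDataset
from .opls import OplsError, _fit_core, _predict_core, select_n_orth, vip_table_from_weights
from .preprocess import ColumnScaler

logger = logging.getLogger(__name__)

CHANCE_ACCURACY = 50.0  # % — two balanced classes


class ValidationError(ValueError):
    pass


@dataclass
class EnsembleResult:
    """Per-repetition external-CV predictive accuracies, in percent."""

    accuracies: np.ndarray
    k: int
    label_mode: str
    seed: int
    group_pair: tuple[str, str]

    @property
    def repetitions(self) -> int:
        return len(self.accuracies)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "accuracies": self.accuracies.tolist(),
            "repetitions": self.repetitions,
            "k": self.k,
            "mean": self.mean,
            "sd": self.sd,
            "label_mode": self.label_mode,
            "seed": self.seed,
            "group_pair": list(self.group_pair),
        }


@dataclass
class EnsembleComparison:
    """Defined-class vs random-class ensemble comparison."""

    ks_statistic: float
    p_value: float
    defined_mean: float
    null_mean: float
    fold_change_over_chance: float
    valid: bool

    def to_dict(self) -> dict:
        return {
            "ks_statistic": self.ks_statistic,
            "p_value": self.p_value,
            "defined_mean": self.defined_mean,
            "null_mean": self.null_mean,
            "fold_change_over_chance": self.fold_change_over_chance,
            "valid": self.valid,
        }


# ---------------------------------------------------------------------
# balancing and fold construction


def balance_groups(
    metadata: pd.DataFrame,
    group_pair: tuple[str, str],
    rng: np.random.Generator,
) -> tuple[list, list]:
    """Equal-size sample-id lists for the two groups.

    All samples of the smaller group are kept; the larger group is
    subsampled uniformly without replacement down to the same size.
    """
    ids = {g: metadata.index[metadata["group"] == g].to_list() for g in group_pair}
    for g, lst in ids.items():
        if len(lst) < 2:
            raise ValidationError(f"group {g!r} has {len(lst)} samples; need >= 2")
    a, b = group_pair
    k = min(len(ids[a]), len(ids[b]))
    out = {}
    for g in group_pair:
        lst = ids[g]
        if len(lst) > k:
            lst = list(rng.choice(lst, size=k, replace=False))
        out[g] = lst
    return out[a], out[b]


def make_folds(
    ids_a: list, ids_b: list, rng: np.random.Generator
) -> list[tuple[object, object]]:
    """k folds, each pairing one sample of each class uniformly at random."""
    if len(ids_a) != len(ids_b):
        raise ValidationError(
            f"balanced input required: {len(ids_a)} vs {len(ids_b)} samples"
        )
    perm_a = rng.permutation(len(ids_a))
    perm_b = rng.permutation(len(ids_b))
    return [(ids_a[i], ids_b[j]) for i, j in zip(perm_a, perm_b)]


# ---------------------------------------------------------------------
# the ensemble engine


def external_cv_ensemble(
    dataset: SpectralDataset,
    group_pair: tuple[str, str] = ("DTH", "control"),
    repetitions: int = 100,
    seed: int = 0,
    label_mode: str = "defined",
    timepoint: int | None = None,
    fluid: str | None = None,
    max_orth: int = 3,
    scale_method: str = "uv",
    collect_vip: bool = False,
):
    """Run the balanced external cross-validation ensemble.

    The dataset's rows are expected to be constant-sum normalized
    (a per-sample operation, so it cannot leak information across the
    train/test split).  Column scaling, orthogonal-component selection
    and model fitting happen inside each training portion only.

    Parameters
    ----------
    label_mode
        "defined" uses the metadata labels; "random" permutes the labels
        over the balanced samples in every repetition (preserving class
        sizes), which produces the chance-level null ensemble.
    collect_vip
        When true, also return the per-model VIP matrix
        (n_models x n_bins; one fitted model per fold per repetition).

    Returns
    -------
    EnsembleResult, or (EnsembleResult, vip_models) with ``collect_vip``.
    """
    if repetitions < 1:
        raise ValidationError("repetitions must be >= 1")
    if label_mode not in ("defined", "random"):
        raise ValidationError(f"label_mode must be 'defined' or 'random', got {label_mode!r}")
    sub = dataset.subset(groups=group_pair, timepoint=timepoint, fluid=fluid)
    meta = sub.metadata
    X_all = sub.intensities
    counts = meta["group"].value_counts()
    k = int(min(counts.get(g, 0) for g in group_pair))
    if k < 3:
        raise ValidationError(
            f"need >= 3 samples per class for internal LOO CV, got {counts.to_dict()}"
        )

    accuracies = np.empty(repetitions)
    vip_models: list[np.ndarray] = []
    for rep in range(repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, rep]))
        ids_a, ids_b = balance_groups(meta, group_pair, rng)
        balanced = list(ids_a) + list(ids_b)
        labels = np.array([0] * len(ids_a) + [1] * len(ids_b))
        if label_mode == "random":
            labels = rng.permutation(labels)
        by_class = (
            [balanced[i] for i in np.flatnonzero(labels == 0)],
            [balanced[i] for i in np.flatnonzero(labels == 1)],
        )
        folds = make_folds(by_class[0], by_class[1], rng)
        code = {sid: labels[balanced.index(sid)] for sid in balanced}
        X = X_all.loc[balanced].to_numpy(dtype=float)
        pos = {sid: i for i, sid in enumerate(balanced)}
        y = np.array([code[sid] for sid in balanced], dtype=float)

        correct = 0
        for test_ids in folds:
            test_idx = [pos[s] for s in test_ids]
            train_mask = np.ones(len(balanced), dtype=bool)
            train_mask[test_idx] = False
            scaler = ColumnScaler(method=scale_method).fit(X[train_mask])
            Xtr = scaler.transform(X[train_mask])
            ytr = y[train_mask]
            m = select_n_orth(Xtr, ytr, max_orth=max_orth)
            w, W_o, P_o, c, y_mean, _, _ = _fit_core(Xtr, ytr, m)
            Xte = scaler.transform(X[test_idx])
            yhat = _predict_core(Xte, w, W_o, P_o, c, y_mean)
            correct += int(((yhat >= 0.5) == (y[test_idx] >= 0.5)).sum())
            if collect_vip:
                vip_models.append(np.sqrt(len(w) * w**2 / (w**2).sum()))
        accuracies[rep] = 100.0 * correct / (2 * k)
        logger.debug(
            "repetition %d/%d (%s): accuracy %.1f%%",
            rep + 1, repetitions, label_mode, accuracies[rep],
        )

    result = EnsembleResult(
        accuracies=accuracies,
        k=k,
        label_mode=label_mode,
        seed=int(seed),
        group_pair=tuple(group_pair),
    )
    logger.info(
        "%s-class ensemble %s: mean %.1f%% (SD %.1f) over %d repetitions, k=%d",
        label_mode, "/".join(group_pair), result.mean, result.sd, repetitions, k,
    )
    if collect_vip:
        return result, np.vstack(vip_models)
    return result


def ensemble_vip(vip_models: np.ndarray, bin_ids) -> pd.DataFrame:
    """Mean per-bin VIP across all models of an ensemble, with ranks."""
    mean_vip = np.asarray(vip_models, dtype=float).mean(axis=0)
    df = pd.DataFrame({"vip": mean_vip}, index=pd.Index(bin_ids, name="bin_id"))
    order = df.sort_values(["vip", "bin_id"], ascending=[False, True]).index
    df.loc[order, "rank"] = np.arange(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    return df


# ---------------------------------------------------------------------
# ensemble comparison


def compare_ensembles(
    defined: EnsembleResult, null: EnsembleResult, alpha: float = 0.05
) -> EnsembleComparison:
    """Two-sample two-sided KS comparison of the two accuracy ensembles.

    Uses the exact small-sample KS distribution when both ensembles have
    at most 100 repetitions, the asymptotic distribution otherwise.  The
    separation is flagged valid when p < alpha and the defined-class mean
    exceeds the null mean.
    """
    a, b = np.asarray(defined.accuracies), np.asarray(null.accuracies)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both ensembles must be non-empty")
    if np.array_equal(a, b):
        d_stat, p = 0.0, 1.0
    else:
        method = "exact" if max(len(a), len(b)) <= 100 else "asymp"
        res = stats.ks_2samp(a, b, method=method)
        d_stat, p = float(res.statistic), float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return EnsembleComparison(
        ks_statistic=d_stat,
        p_value=p,
        defined_mean=defined.mean,
        null_mean=null.mean,
        fold_change_over_chance=accuracy_fold_change(defined.mean),
        valid=bool(p < alpha and defined.mean > null.mean),
    )


def accuracy_fold_change(mean_accuracy: float) -> float:
    """Mean accuracy (%) normalized to the 50% two-class chance level."""
    if not 0.0 <= mean_accuracy <= 100.0:
        raise ValidationError(f"accuracy must be in [0, 100], got {mean_accuracy}")
    return mean_accuracy / CHANCE_ACCURACY
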