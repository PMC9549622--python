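"""Two-class OPLS-DA: fitting, prediction, component selection, VIP.

Orthogonal projections to latent structures discriminant analysis splits
the predictor variation into one class-predictive component and m
components orthogonal to the class vector.  For a two-class problem with
classes coded y in {0, 1} and column-scaled X, the model is fitted by the
standard O-PLS NIPALS recursion:

    w   = X' y_c / ||X' y_c||                (predictive weights)
    repeat m times:
        t    = X w
        p    = X' t / (t' t)
        w_o  = p - (w' p) w,  normalized     (orthogonal weights)
        t_o  = X w_o
        p_o  = X' t_o / (t_o' t_o)
        X    = X - t_o p_o'                  (deflation)
    t   = X w                                (final predictive scores)
    c   = y_c' t / (t' t)                    (y loading)

with y_c the centred class vector.  Prediction deflates a new sample by
the stored orthogonal components and returns yhat = (x . w) c + y_mean,
thresholded at 0.5.  With m = 0 the model is exactly a one-component
PLS1, which is the cross-check used in the tests.

The number of orthogonal components is chosen on the training set alone
by leave-one-out cross-validation: m grows from 0 while adding a
component improves LOO accuracy by more than a tolerance.

The VIP (variable importance in projection) score of bin j is computed
from the predictive weights, VIP_j = sqrt(n_bins * w_j^2 / sum_k w_k^2);
its squares average exactly 1, so VIP > 1 marks above-average
contribution to the discrimination.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ColumnScaler


class OplsError(ValueError):
    pass


# ---------------------------------------------------------------------
# bare-array core (hot path inside cross-validation loops)


def _fit_core(X: np.ndarray, y: np.ndarray, n_orth: int):
    """Fit on pre-scaled arrays; returns (w, W_o, P_o, c, y_mean).

    Raises OplsError when the predictive direction or an orthogonal score
    degenerates (rank-deficient X for the requested n_orth).
    """
    n, p = X.shape
    y_mean = y.mean()
    y_c = y - y_mean
    Xd = X
    w = Xd.T @ y_c
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise OplsError("degenerate fit: X carries no covariance with the class vector")
    w /= nw
    W_o = np.empty((p, n_orth))
    P_o = np.empty((p, n_orth))
    for j in range(n_orth):
        t = Xd @ w
        tt = t @ t
        if tt < 1e-24:
            raise OplsError(f"rank deficiency: no variation left for component {j + 1}")
        p_load = Xd.T @ t / tt
        w_o = p_load - (w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-10:
            raise OplsError(
                f"rank deficiency: orthogonal component {j + 1} exceeds the rank of X"
            )
        w_o /= n_wo
        t_o = Xd @ w_o
        tt_o = t_o @ t_o
        if tt_o < 1e-24:
            raise OplsError(
                f"rank deficiency: orthogonal component {j + 1} has zero score variance"
            )
        p_o = Xd.T @ t_o / tt_o
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, j] = w_o
        P_o[:, j] = p_o
    t = Xd @ w
    tt = t @ t
    if tt < 1e-24:
        raise OplsError("degenerate fit: predictive scores have zero variance")
    c = (y_c @ t) / tt
    return w, W_o, P_o, c, y_mean, Xd, t


def _deflate(X: np.ndarray, W_o: np.ndarray, P_o: np.ndarray) -> np.ndarray:
    Xd = np.array(X, dtype=float, copy=True)
    for j in range(W_o.shape[1]):
        t_o = Xd @ W_o[:, j]
        Xd -= np.outer(t_o, P_o[:, j])
    return Xd


def _predict_core(X, w, W_o, P_o, c, y_mean) -> np.ndarray:
    Xd = _deflate(np.atleast_2d(X), W_o, P_o)
    return (Xd @ w) * c + y_mean


# ---------------------------------------------------------------------
# public model object


@dataclass
class OplsdaModel:
    """A fitted two-class OPLS-DA model.

    ``class_codes`` maps the two group labels onto the codes {0, 1}; the
    decision rule assigns the code-1 class when the continuous prediction
    is at or above ``threshold``.  ``scaler`` carries the training-set
    column statistics so held-out samples can be scaled consistently.
    """

    weights: np.ndarray
    orth_weights: np.ndarray
    orth_loadings: np.ndarray
    y_loading: float
    y_mean: float
    scores: np.ndarray
    orth_scores: np.ndarray
    class_codes: dict[str, int]
    threshold: float = 0.5
    scaler: ColumnScaler | None = None
    bin_ids: list[str] | None = None

    @property
    def n_orth(self) -> int:
        return self.orth_weights.shape[1]

    @property
    def n_bins(self) -> int:
        return self.weights.shape[0]

    def predict(self, X_scaled) -> tuple[np.ndarray, np.ndarray]:
        """Continuous predictions and class labels for pre-scaled samples."""
        X = np.atleast_2d(np.asarray(X_scaled, dtype=float))
        if X.shape[1] != self.n_bins:
            raise OplsError(
                f"bin dimension mismatch: model has {self.n_bins}, input has {X.shape[1]}"
            )
        yhat = _predict_core(
            X, self.weights, self.orth_weights, self.orth_loadings,
            self.y_loading, self.y_mean,
        )
        inv = {v: k for k, v in self.class_codes.items()}
        labels = np.array([inv[1] if v >= self.threshold else inv[0] for v in yhat])
        return yhat, labels

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "orth_weights": self.orth_weights.tolist(),
            "orth_loadings": self.orth_loadings.tolist(),
            "y_loading": self.y_loading,
            "y_mean": self.y_mean,
            "class_codes": self.class_codes,
            "threshold": self.threshold,
            "bin_ids": self.bin_ids,
            "scaler": None
            if self.scaler is None
            else {
                "method": self.scaler.method,
                "means": self.scaler.means_.tolist(),
                "scales": self.scaler.scales_.tolist(),
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OplsdaModel":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        d = json.loads(text)
        scaler = None
        if d["scaler"] is not None:
            scaler = ColumnScaler(method=d["scaler"]["method"])
            scaler.means_ = np.asarray(d["scaler"]["means"], dtype=float)
            scaler.scales_ = np.asarray(d["scaler"]["scales"], dtype=float)
        p = len(d["weights"])
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            orth_weights=np.asarray(d["orth_weights"], dtype=float).reshape(p, -1),
            orth_loadings=np.asarray(d["orth_loadings"], dtype=float).reshape(p, -1),
            y_loading=float(d["y_loading"]),
            y_mean=float(d["y_mean"]),
            scores=np.empty(0),
            orth_scores=np.empty((0, 0)),
            class_codes={k: int(v) for k, v in d["class_codes"].items()},
            threshold=float(d["threshold"]),
            scaler=scaler,
            bin_ids=d.get("bin_ids"),
        )


def encode_labels(labels, class_codes: dict[str, int] | None = None):
    """Map two class labels onto codes {0, 1} (sorted order by default)."""
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise OplsError(f"exactly two classes required, got {uniq}")
    if class_codes is None:
        class_codes = {uniq[0]: 0, uniq[1]: 1}
    y = np.array([class_codes[v] for v in labels], dtype=float)
    return y, class_codes


def fit_oplsda(
    X_scaled,
    y,
    n_orth: int = 0,
    class_codes: dict[str, int] | None = None,
    scaler: ColumnScaler | None = None,
    bin_ids=None,
) -> OplsdaModel:
    """Fit a two-class OPLS-DA model on a column-scaled matrix.

    ``y`` may be 0/1 codes or a pair of string labels.  Requires at least
    two samples per class and n_orth within the rank of X.
    """
    X = np.asarray(X_scaled, dtype=float)
    if X.ndim != 2:
        raise OplsError("X must be 2-D")
    yarr = np.asarray(y)
    if yarr.dtype.kind in "OUS":
        y_codes, class_codes = encode_labels(yarr, class_codes)
    else:
        y_codes = yarr.astype(float)
        vals = sorted(set(y_codes.tolist()))
        if vals not in ([0.0, 1.0],):
            raise OplsError(f"numeric y must contain exactly the codes 0 and 1, got {vals}")
        if class_codes is None:
            class_codes = {"0": 0, "1": 1}
    counts = [(y_codes == v).sum() for v in (0.0, 1.0)]
    if min(counts) < 2:
        raise OplsError(f"each class needs >= 2 samples, got counts {counts}")
    if n_orth < 0:
        raise OplsError("n_orth must be >= 0")
    max_rank = min(X.shape[0] - 1, X.shape[1]) - 1
    if n_orth > max(0, max_rank):
        raise OplsError(
            f"n_orth={n_orth} exceeds the usable rank of a {X.shape} matrix"
        )
    w, W_o, P_o, c, y_mean, Xd, t = _fit_core(X, y_codes, n_orth)
    T_o = np.column_stack([_deflate_scores(X, W_o, P_o, j) for j in range(n_orth)]) \
        if n_orth else np.empty((X.shape[0], 0))
    return OplsdaModel(
        weights=w,
        orth_weights=W_o,
        orth_loadings=P_o,
        y_loading=float(c),
        y_mean=float(y_mean),
        scores=t,
        orth_scores=T_o,
        class_codes=class_codes,
        scaler=scaler,
        bin_ids=list(bin_ids) if bin_ids is not None else None,
    )


def _deflate_scores(X, W_o, P_o, j):
    Xd = np.array(X, dtype=float, copy=True)
    for i in range(j):
        t_o = Xd @ W_o[:, i]
        Xd -= np.outer(t_o, P_o[:, i])
    return Xd @ W_o[:, j]


def predict(model: OplsdaModel, X_new_scaled):
    """Functional alias for :meth:`OplsdaModel.predict`."""
    return model.predict(X_new_scaled)


# ---------------------------------------------------------------------
# component selection


def _loo_accuracy(X: np.ndarray, y: np.ndarray, n_orth: int) -> float:
    n = X.shape[0]
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            w, W_o, P_o, c, y_mean, _, _ = _fit_core(X[mask], y[mask], n_orth)
        except OplsError:
            mask[i] = True
            return -np.inf  # this m is not fittable on the folds
        yhat = _predict_core(X[i], w, W_o, P_o, c, y_mean)[0]
        correct += int((yhat >= 0.5) == (y[i] >= 0.5))
        mask[i] = True
    return correct / n


def select_n_orth(
    X_scaled, y, max_orth: int = 3, tol: float = 0.01
) -> int:
    """Pick the number of orthogonal components by internal LOO CV.

    Returns the smallest m in [0, max_orth] such that moving to m+1 does
    not improve leave-one-out accuracy by more than ``tol`` (default one
    accuracy point).  Runs entirely within the provided training data.
    Degenerate X (no class-covariant variation) returns 0 with a warning.
    """
    X = np.asarray(X_scaled, dtype=float)
    yarr = np.asarray(y)
    if yarr.dtype.kind in "OUS":
        yarr, _ = encode_labels(yarr)
    else:
        yarr = yarr.astype(float)
    counts = [(yarr == v).sum() for v in (0.0, 1.0)]
    if min(counts) < 3:
        raise OplsError(f"LOO selection needs >= 3 samples per class, got {counts}")
    if max_orth < 0:
        raise OplsError("max_orth must be >= 0")
    if np.allclose(X.std(axis=0), 0):
        warnings.warn("zero-variance training matrix; using 0 orthogonal components",
                      RuntimeWarning, stacklevel=2)
        return 0
    if max_orth == 0:
        return 0
    acc_m = _loo_accuracy(X, yarr, 0)
    if not np.isfinite(acc_m):
        warnings.warn("degenerate LOO fits; using 0 orthogonal components",
                      RuntimeWarning, stacklevel=2)
        return 0
    for m in range(max_orth):
        acc_next = _loo_accuracy(X, yarr, m + 1)
        if acc_next - acc_m <= tol:
            return m
        acc_m = acc_next
    return max_orth


# ---------------------------------------------------------------------
# VIP


def vip_scores(model: OplsdaModel, bin_ids=None) -> pd.DataFrame:
    """Per-bin VIP table: columns ``vip`` and ``rank`` (1 = most important).

    Computed from the predictive weight vector only; ties in VIP are
    broken by ascending bin id so ranks are always a permutation of
    1..n_bins.
    """
    if bin_ids is None:
        bin_ids = model.bin_ids
    if bin_ids is None:
        bin_ids = [f"bin_{j:03d}" for j in range(model.n_bins)]
    return vip_table_from_weights(model.weights, bin_ids)


def vip_table_from_weights(weights: np.ndarray, bin_ids) -> pd.DataFrame:
    w2 = np.asarray(weights, dtype=float) ** 2
    vip = np.sqrt(len(w2) * w2 / w2.sum())
    df = pd.DataFrame({"vip": vip}, index=pd.Index(bin_ids, name="bin_id"))
    order = df.sort_values(["vip", "bin_id"], ascending=[False, True]).index
    df.loc[order, "rank"] = np.arange(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    return df
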