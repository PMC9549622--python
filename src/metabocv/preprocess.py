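"""Spectral binning, constant-sum normalization and column scaling.

The classifier consumes a sample x bin matrix in which (i) each spectrum
has been reduced to bin integrals, (ii) each sample has been rescaled to a
constant total (removing overall-concentration differences between
animals), and (iii) each column has been centred and, by default, scaled
to unit variance.  Constant-sum normalization is a per-sample operation
and may be applied to the whole matrix up front; column scaling is fitted
on training data only and applied to held-out samples with the stored
parameters, so the external cross-validation never leaks test-set
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------
# binning


@dataclass(frozen=True)
class BinningScheme:
    """Uniform binning of a ppm axis with exclusion windows.

    Default: 0.04-ppm bins over [0.2, 10.0] ppm with the water region
    [4.5, 5.0] ppm excluded — conventional choices for 1H NMR metabolomics
    of biofluids; all three are configurable.
    """

    bin_width: float = 0.04
    ppm_range: tuple[float, float] = (0.2, 10.0)
    exclusion_windows: tuple[tuple[float, float], ...] = ((4.5, 5.0),)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise PreprocessError(f"bin_width must be > 0, got {self.bin_width}")
        lo, hi = self.ppm_range
        if not lo < hi:
            raise PreprocessError(f"ppm_range must be increasing, got {self.ppm_range}")
        wins = sorted(self.exclusion_windows)
        for a, b in wins:
            if not a < b:
                raise PreprocessError(f"bad exclusion window ({a}, {b})")
            if a < lo or b > hi:
                raise PreprocessError(
                    f"exclusion window ({a}, {b}) outside ppm_range {self.ppm_range}"
                )
        for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
            if b1 > a2:
                raise PreprocessError(
                    f"overlapping exclusion windows ({a1}, {b1}) and ({a2}, {b2})"
                )

    def edges(self) -> np.ndarray:
        """Bin edges from the low end of the range, last partial bin dropped."""
        lo, hi = self.ppm_range
        n = int(np.floor((hi - lo) / self.bin_width + 1e-9))
        return lo + self.bin_width * np.arange(n + 1)

    def retained_bins(self) -> tuple[np.ndarray, np.ndarray]:
        """(left edges, right edges) of bins not touching an exclusion window."""
        e = self.edges()
        left, right = e[:-1], e[1:]
        keep = np.ones(len(left), dtype=bool)
        for a, b in self.exclusion_windows:
            keep &= (right <= a) | (left >= b)
        return left[keep], right[keep]


def bin_spectrum(
    ppm: np.ndarray, intensity: np.ndarray, scheme: BinningScheme
) -> pd.Series:
    """Integrate a spectrum over the scheme's retained bins.

    The spectrum is treated as piecewise linear between grid points and
    each bin value is the exact integral of that interpolant over the
    bin's ppm interval (trapezoidal rule with interpolated endpoints), so
    binning is a linear operator on the intensity vector.  Returns a
    Series labelled by bin-centre ppm.
    """
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if ppm.ndim != 1 or ppm.shape != intensity.shape or len(ppm) < 2:
        raise PreprocessError("ppm and intensity must be equal-length 1-D arrays")
    steps = np.diff(ppm)
    if not (steps > 0).all():
        raise PreprocessError("ppm axis must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=0):
        raise PreprocessError("ppm axis must be a uniform grid")

    left, right = scheme.retained_bins()
    inside = (left >= ppm[0]) & (right <= ppm[-1])
    left, right = left[inside], right[inside]
    if len(left) == 0:
        raise PreprocessError("no retained bin lies inside the spectrum's ppm range")

    # cumulative integral of the piecewise-linear interpolant at grid points,
    # corrected at bin edges by exact partial-trapezoid terms
    def antiderivative(x: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (intensity[1:] + intensity[:-1]) * steps)])
        idx = np.clip(np.searchsorted(ppm, x, side="right") - 1, 0, len(ppm) - 2)
        x0 = ppm[idx]
        y0 = intensity[idx]
        slope = (intensity[idx + 1] - y0) / steps[idx]
        dx = x - x0
        return cum[idx] + y0 * dx + 0.5 * slope * dx**2

    values = antiderivative(right) - antiderivative(left)
    centres = 0.5 * (left + right)
    return pd.Series(values, index=pd.Index(np.round(centres, 6), name="ppm_centre"))


# ---------------------------------------------------------------------
# normalization


def constant_sum_normalize(X, total: float = 1.0):
    """Rescale each row (sample) so its entries sum to ``total``.

    Accepts a DataFrame or 2-D array with non-negative entries; rows with
    zero sum are rejected by name/position.  Scale-invariant: a sample
    multiplied by any positive constant normalizes to the same vector.
    """
    df_in = isinstance(X, pd.DataFrame)
    arr = X.to_numpy(dtype=float) if df_in else np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise PreprocessError("expected a 2-D matrix")
    if (arr < 0).any():
        raise PreprocessError("constant-sum normalization requires non-negative entries")
    sums = arr.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        labels = list(X.index[bad]) if df_in else bad.tolist()
        raise PreprocessError(f"zero-sum rows cannot be normalized: {labels}")
    out = arr * (total / sums)[:, None]
    if df_in:
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


# ---------------------------------------------------------------------
# column scaling


@dataclass
class ColumnScaler:
    """Column centring/scaling fitted on training data.

    method "uv": subtract the column mean and divide by the sample SD
    (n-1 denominator); "center": subtract the mean only.  Zero-variance
    columns under "uv" keep a unit divisor and trigger a warning rather
    than an error — on small training folds a bin can be constant by
    chance and must still pass through.
    """

    method: str = "uv"
    means_: np.ndarray | None = None
    scales_: np.ndarray | None = None

    def fit(self, X) -> "ColumnScaler":
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise PreprocessError("column scaling needs a matrix with >= 2 rows")
        if self.method not in ("uv", "center"):
            raise PreprocessError(f"unknown scaling method {self.method!r}")
        self.means_ = arr.mean(axis=0)
        if self.method == "uv":
            sd = arr.std(axis=0, ddof=1)
            zero = sd == 0
            if zero.any():
                warnings.warn(
                    f"{int(zero.sum())} zero-variance column(s) kept with unit divisor",
                    RuntimeWarning,
                    stacklevel=2,
                )
                sd = np.where(zero, 1.0, sd)
            self.scales_ = sd
        else:
            self.scales_ = np.ones(arr.shape[1])
        return self

    def transform(self, X):
        if self.means_ is None:
            raise PreprocessError("scaler not fitted")
        arr = np.asarray(X, dtype=float)
        out = (arr - self.means_) / self.scales_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def inverse_transform(self, X):
        if self.means_ is None:
            raise PreprocessError("scaler not fitted")
        arr = np.asarray(X, dtype=float)
        out = arr * self.scales_ + self.means_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def scale_columns(X, method: str = "uv"):
    """Fit a :class:`ColumnScaler` on X and return (X_scaled, scaler)."""
    scaler = ColumnScaler(method=method).fit(X)
    return scaler.transform(X), scaler
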