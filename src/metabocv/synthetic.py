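"""Synthetic cohort generator.

The raw spectra behind the original rat study are not publicly deposited,
so this module generates bin tables with the statistical structure the
analysis assumes: heterogeneous baseline bin abundances, multiplicative
log-normal measurement noise, a small set of marker bins whose mean is
reduced in lesioned (DTH) animals by a timepooint-dependent fraction that
is largest at day 12, and per-animal histology/NfL covariates correlated
with the marker-bin deviation at a tunable Pearson r.

Everything is driven by a single integer seed: the same
:class:`SyntheticConfig` always reproduces the same cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import (
    COVARIATE_COLUMNS,
    GROUPS,
    TIMEPOINTS,
    SpectralDataset,
)

#: Bin counts matching the two acquisition schemes of the original assay.
N_BINS_SERUM = 194
N_BINS_CSF = 122

#: Mean covariate levels by group.  Lesioned animals show elevated glial
#: densities and NfL and non-zero loss areas; unlesioned animals have zero
#: loss areas by definition.  Magnitudes follow the units of
#: :class:`~metabocv.dataset.CovariateRecord`.
_COVARIATE_LEVELS = {
    # covariate: (DTH mean, control/naive mean, SD, sign vs covariate_corr)
    "iba1_density": (800.0, 300.0, 120.0, +1),
    "gfap_density": (600.0, 200.0, 100.0, +1),
    "mbp_loss_area": (1.5, 0.0, 0.4, -1),
    "nfh_loss_area": (1.2, 0.0, 0.35, -1),
    "nfl_serum": (38.5, 17.4, 8.0, +1),
    "nfl_csf": (1312.0, 475.8, 300.0, +1),
}


def _default_marker_bins(n_bins: int) -> tuple[int, ...]:
    # five bins spread evenly through the spectrum
    return tuple(int(round((i + 1) * n_bins / 6)) for i in range(5))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_per_group
        Animals per group per timepoint (>= 3; default 8, consistent with
        the pooled n of roughly 24 lesioned animals over three timepoints
        seen in this kind of study).
    n_bins
        Number of spectral bins; 194 for serum, 122 for CSF.
    fluid
        Body fluid label stamped into the metadata.
    marker_bins
        Column indices carrying the group effect.
    effect_by_timepoint
        Fractional mean reduction of the marker bins in DTH animals per
        timepoint, each in [0, 1).  The default decays from day 12 to
        day 60, mirroring an early-peaking metabolic perturbation.
    noise_cv
        Coefficient of variation of the multiplicative log-normal noise.
    covariate_corr
        Target Pearson correlation between an animal's marker-bin
        deviation and its glial/NfL covariates (loss-area covariates get
        the opposite sign).
    baseline_log10_range
        log10 range the per-bin baseline means are drawn from; the default
        spans two orders of magnitude.
    seed
        Master seed; identical configs produce identical cohorts.
    """

    n_per_group: int = 8
    n_bins: int = N_BINS_SERUM
    fluid: str = "serum"
    marker_bins: tuple[int, ...] | None = None
    effect_by_timepoint: dict[int, float] = field(
        default_factory=lambda: {12: 0.30, 28: 0.15, 60: 0.05}
    )
    noise_cv: float = 0.1
    covariate_corr: float = -0.55
    baseline_log10_range: tuple[float, float] = (0.0, 2.0)
    groups: tuple[str, ...] = GROUPS
    timepoints: tuple[int, ...] = TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError(f"n_per_group must be >= 3, got {self.n_per_group}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if self.noise_cv <= 0:
            raise ValueError(f"noise_cv must be > 0, got {self.noise_cv}")
        if not (-1.0 <= self.covariate_corr <= 1.0):
            raise ValueError("covariate_corr must lie in [-1, 1]")
        if self.marker_bins is None:
            object.__setattr__(self, "marker_bins", _default_marker_bins(self.n_bins))
        bad = [b for b in self.marker_bins if not 0 <= b < self.n_bins]
        if bad:
            raise ValueError(f"marker_bins out of range [0, {self.n_bins}): {bad}")
        for t, e in self.effect_by_timepoint.items():
            if not 0.0 <= e < 1.0:
                raise ValueError(f"effect at timepoint {t} must be in [0, 1), got {e}")
        unknown_t = set(self.effect_by_timepoint) - set(self.timepoints)
        if unknown_t:
            raise ValueError(f"effects given for unknown timepoints {sorted(unknown_t)}")


def csf_config(**overrides) -> SyntheticConfig:
    """A :class:`SyntheticConfig` at the CSF dimensionality (122 bins)."""
    base = dict(n_bins=N_BINS_CSF, fluid="CSF")
    base.update(overrides)
    return SyntheticConfig(**base)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Generate one full cohort: intensities, metadata and covariates.

    The intensity of bin j in animal i is

        x_ij = baseline_j * g_ij * exp(eps_ij),    eps_ij ~ N(-s^2/2, s^2)

    with s chosen so the multiplicative noise has the configured CV and
    unit mean, and g_ij = 1 - effect[t] when animal i is a DTH animal at
    timepoint t and j is a marker bin, else 1.  Covariates are linear in
    each animal's standardized mean marker-bin log-deviation z_i:
    a latent r*z_i + sqrt(1-r^2)*eta_i is mapped onto each covariate's
    group mean and SD, so the realized covariate / marker correlation
    targets ``covariate_corr``.

    Returns the dataset and a covariate table indexed by sample id.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.baseline_log10_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=cfg.n_bins)
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))

    marker = np.asarray(cfg.marker_bins, dtype=int)
    rows, sample_ids, meta_rows = [], [], []
    z_scores = []
    for t in cfg.timepoints:
        effect = cfg.effect_by_timepoint.get(t, 0.0)
        for group in cfg.groups:
            factor = np.ones(cfg.n_bins)
            if group == "DTH":
                factor[marker] = 1.0 - effect
            for a in range(cfg.n_per_group):
                eps = rng.normal(-0.5 * sigma**2, sigma, size=cfg.n_bins)
                rows.append(baseline * factor * np.exp(eps))
                # standardized mean marker-bin log-deviation of this animal
                zm = (eps[marker].mean() + 0.5 * sigma**2) / (sigma / np.sqrt(len(marker)))
                z_scores.append(zm)
                sample_ids.append(f"{cfg.fluid}-d{t}-{group}-{a + 1:02d}")
                meta_rows.append({"group": group, "timepoint": t, "fluid": cfg.fluid})

    bin_ids = [f"bin_{j:03d}" for j in range(cfg.n_bins)]
    X = pd.DataFrame(np.vstack(rows), index=pd.Index(sample_ids, name="sample_id"),
                     columns=bin_ids)
    meta = pd.DataFrame(meta_rows, index=X.index)
    dataset = SpectralDataset(X, meta)

    cov = _generate_covariates(cfg, meta, np.asarray(z_scores), rng)
    return dataset, cov


def _generate_covariates(
    cfg: SyntheticConfig,
    meta: pd.DataFrame,
    z: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Covariates as noisy linear readouts of the marker-bin z-score."""
    r = cfg.covariate_corr
    n = len(meta)
    is_dth = (meta["group"] == "DTH").to_numpy()
    out = {}
    for name, (mu_dth, mu_ctrl, sd, sign) in _COVARIATE_LEVELS.items():
        latent = sign * r * z + np.sqrt(1.0 - r**2) * rng.normal(size=n)
        values = np.where(is_dth, mu_dth, mu_ctrl) + sd * latent
        if name in ("mbp_loss_area", "nfh_loss_area"):
            # tissue loss is defined only in lesioned animals
            values = np.where(is_dth, values, 0.0)
        out[name] = np.clip(values, 0.0, None)
    return pd.DataFrame(out, index=meta.index)[list(COVARIATE_COLUMNS)]


def generate_null_cohort(config: SyntheticConfig) -> SpectralDataset:
    """Cohort with every group effect forced to zero.

    Group labels then carry no information about the data, which makes
    the output the natural input for chance-level calibration of the
    cross-validation ensembles.
    """
    null_cfg = replace(
        config, effect_by_timepoint={t: 0.0 for t in config.effect_by_timepoint}
    )
    dataset, _ = generate_cohort(null_cfg)
    return dataset
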