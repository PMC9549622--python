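"""End-to-end orchestration: the full discriminative-metabolomics analysis.

`run_full_analysis` reproduces the study workflow on any conforming
dataset: constant-sum normalization, defined-class and random-class
cross-validation ensembles per timepoint, their Kolmogorov-Smirnov
comparison with a validity flag, fold-change-over-chance summaries,
ensemble VIP ranking with the top two bins highlighted, control-normalized
trajectories of those bins across timepoints and, when covariates are
supplied, the Pearson correlation matrix between the top bins'
fold-changes and the histology/NfL covariates.  Every number in the
report is a deterministic function of the inputs and the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import SpectralDataset, read_covariates, read_dataset
from .preprocess import constant_sum_normalize
from .stats import marker_trajectory, normalize_to_control, pearson_corr_matrix
from .validation import compare_ensembles, ensemble_vip, external_cv_ensemble

logger = logging.getLogger(__name__)

N_TOP_BINS = 2


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    matrix_path: str
    metadata_path: str
    covariates_path: str | None = None
    group_pair: tuple[str, str] = ("DTH", "control")
    timepoints: tuple[int, ...] | None = None  # None = all present
    fluid: str | None = None
    repetitions: int = 100
    seed: int = 0
    scale_method: str = "uv"
    max_orth: int = 3
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "group_pair" in data:
            data["group_pair"] = tuple(data["group_pair"])
        if data.get("timepoints") is not None:
            data["timepoints"] = tuple(int(t) for t in data["timepoints"])
        return cls(**data)


def analyze_dataset(
    dataset: SpectralDataset,
    covariates: pd.DataFrame | None = None,
    group_pair: tuple[str, str] = ("DTH", "control"),
    timepoints: tuple[int, ...] | None = None,
    fluid: str | None = None,
    repetitions: int = 100,
    seed: int = 0,
    scale_method: str = "uv",
    max_orth: int = 3,
) -> dict:
    """Run the whole analysis in memory and return the report dict."""
    if timepoints is None:
        timepoints = tuple(sorted(dataset.metadata["timepoint"].astype(int).unique()))
    norm = dataset.with_intensities(constant_sum_normalize(dataset.intensities))

    per_timepoint = {}
    vip_tables = {}
    for i, t in enumerate(timepoints):
        logger.info("timepoint %s: defined-class ensemble", t)
        defined, vips = external_cv_ensemble(
            norm, group_pair, repetitions=repetitions, seed=seed + 1000 * i,
            label_mode="defined", timepoint=t, fluid=fluid,
            max_orth=max_orth, scale_method=scale_method, collect_vip=True,
        )
        logger.info("timepoint %s: random-class ensemble", t)
        null = external_cv_ensemble(
            norm, group_pair, repetitions=repetitions, seed=seed + 1000 * i + 500,
            label_mode="random", timepoint=t, fluid=fluid,
            max_orth=max_orth, scale_method=scale_method,
        )
        comparison = compare_ensembles(defined, null)
        vip = ensemble_vip(vips, norm.bin_ids)
        vip_tables[t] = vip
        top = vip.sort_values("rank").head(N_TOP_BINS)
        per_timepoint[str(t)] = {
            "defined": defined.to_dict(),
            "null": null.to_dict(),
            "comparison": comparison.to_dict(),
            "top_bins": top.index.tolist(),
            "top_vip": top["vip"].tolist(),
        }

    # top bins from the timepoint with the strongest separation
    best_t = max(
        timepoints, key=lambda t: per_timepoint[str(t)]["comparison"]["defined_mean"]
    )
    top_bins = per_timepoint[str(best_t)]["top_bins"]

    trajectories = {}
    if len(timepoints) >= 2:
        sub = norm if fluid is None else norm.subset(fluid=fluid)
        for b in top_bins:
            traj = marker_trajectory(sub, b, group=group_pair[0], control=group_pair[1])
            trajectories[b] = {
                "normalized_means": {str(k): float(v)
                                     for k, v in traj.normalized_means.items()},
                "anova_F": traj.anova.f_statistic,
                "anova_p": traj.anova.p_value,
                "returns_toward_control": traj.returns_toward_control,
            }

    correlations = None
    if covariates is not None:
        correlations = _top_bin_covariate_correlations(
            norm, covariates, top_bins, group_pair, fluid
        )

    return {
        "seed": int(seed),
        "group_pair": list(group_pair),
        "repetitions": int(repetitions),
        "timepoints": [int(t) for t in timepoints],
        "per_timepoint": per_timepoint,
        "strongest_timepoint": int(best_t),
        "top_bins": top_bins,
        "trajectories": trajectories,
        "correlations": correlations,
        "_vip_tables": vip_tables,  # stripped before JSON serialization
    }


def _top_bin_covariate_correlations(
    norm: SpectralDataset,
    covariates: pd.DataFrame,
    top_bins: list[str],
    group_pair: tuple[str, str],
    fluid: str | None,
) -> dict:
    """Correlate control-normalized top-bin values (lesioned animals pooled
    over timepoints) with the covariates."""
    sub = norm if fluid is None else norm.subset(fluid=fluid)
    meta = sub.metadata
    dth = meta["group"] == group_pair[0]
    ctl = meta["group"] == group_pair[1]
    table = {}
    for b in top_bins:
        fc = normalize_to_control(
            sub.intensities.loc[dth, b].to_numpy(),
            meta.loc[dth, "timepoint"].astype(int).to_numpy(),
            sub.intensities.loc[ctl, b].to_numpy(),
            meta.loc[ctl, "timepoint"].astype(int).to_numpy(),
        )
        table[b] = pd.Series(fc["fold_change"].to_numpy(), index=meta.index[dth])
    frame = pd.DataFrame(table)
    cov = covariates.reindex(frame.index)
    joined = pd.concat([frame, cov], axis=1).dropna(axis=1, how="all")
    cm = pearson_corr_matrix(joined)
    return cm.to_dict()


def run_full_analysis(config: RunConfig) -> dict:
    """Read inputs, run :func:`analyze_dataset`, write the report files.

    Writes ``report.json`` (canonical output), per-timepoint accuracy
    CSVs and VIP CSVs into ``config.out_dir`` and returns the report.
    """
    dataset = read_dataset(config.matrix_path, config.metadata_path)
    covariates = (
        read_covariates(config.covariates_path) if config.covariates_path else None
    )
    report = analyze_dataset(
        dataset,
        covariates,
        group_pair=config.group_pair,
        timepoints=config.timepoints,
        fluid=config.fluid,
        repetitions=config.repetitions,
        seed=config.seed,
        scale_method=config.scale_method,
        max_orth=config.max_orth,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vip_tables = report.pop("_vip_tables")
    for t, vip in vip_tables.items():
        vip.to_csv(out / f"vip_t{t}.csv")
        acc = pd.DataFrame(
            {
                "defined": report["per_timepoint"][str(t)]["defined"]["accuracies"],
                "random": report["per_timepoint"][str(t)]["null"]["accuracies"],
            }
        )
        acc.to_csv(out / f"accuracies_t{t}.csv", index_label="repetition")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", out / "report.json")
    return report
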