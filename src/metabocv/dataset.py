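"""Central data container for binned NMR spectra and its CSV round-trip.

A :class:`SpectralDataset` holds a sample x bin intensity matrix together
with per-sample metadata (experimental group, timepoint in days post
induction, and body fluid).  All downstream stages — normalization, the
OPLS-DA cross-validation engine and the univariate layer — consume this
object, so validation is strict: unique identifiers, complete metadata and
a closed vocabulary for the categorical fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Allowed experimental groups.  "DTH" animals carry the focal
#: delayed-type-hypersensitivity brain lesion; "control" animals received
#: the sham procedure; "naive" animals received no intervention.
GROUPS = ("DTH", "control", "naive")

#: Sampling timepoints, days after lesion induction.
TIMEPOINTS = (12, 28, 60)

#: Body fluids with their own spectral acquisition schemes.
FLUIDS = ("serum", "CSF")

METADATA_COLUMNS = ("group", "timepoint", "fluid")


class DatasetError(ValueError):
    """Raised when a dataset violates its structural contract."""


@dataclass
class SpectralDataset:
    """Sample x bin intensity matrix plus per-sample metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with one column per spectral bin,
        in arbitrary units.  Values must be finite; raw (pre-normalization)
        intensities are strictly positive.
    metadata
        DataFrame indexed by sample id with columns ``group``,
        ``timepoint`` and ``fluid``.  Every intensity row must have a
        metadata row and vice versa.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        X, meta = self.intensities, self.metadata
        if X.index.has_duplicates:
            dupes = X.index[X.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample ids: {dupes}")
        if X.columns.has_duplicates:
            dupes = X.columns[X.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate bin ids: {dupes}")
        vals = X.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = X.columns[[not np.issubdtype(d, np.number) for d in X.dtypes]]
            raise DatasetError(f"non-numeric intensity columns: {list(bad)}")
        if not np.isfinite(vals).all():
            rows = X.index[~np.isfinite(vals).all(axis=1)].tolist()
            raise DatasetError(f"missing or non-finite intensities in samples: {rows}")
        missing_meta = X.index.difference(meta.index).tolist()
        if missing_meta:
            raise DatasetError(f"samples without metadata: {missing_meta}")
        orphan = meta.index.difference(X.index).tolist()
        if orphan:
            raise DatasetError(f"metadata rows without intensities: {orphan}")
        for col in METADATA_COLUMNS:
            if col not in meta.columns:
                raise DatasetError(f"metadata missing required column {col!r}")
        bad_group = set(meta["group"]) - set(GROUPS)
        if bad_group:
            raise DatasetError(
                f"unknown group labels {sorted(bad_group)}; allowed: {list(GROUPS)}"
            )
        bad_tp = set(meta["timepoint"].astype(int)) - set(TIMEPOINTS)
        if bad_tp:
            raise DatasetError(
                f"unknown timepoints {sorted(bad_tp)}; allowed: {list(TIMEPOINTS)}"
            )
        bad_fluid = set(meta["fluid"]) - set(FLUIDS)
        if bad_fluid:
            raise DatasetError(
                f"unknown fluids {sorted(bad_fluid)}; allowed: {list(FLUIDS)}"
            )

    # -- convenience --------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def bin_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_samples(self) -> int:
        return len(self.intensities)

    @property
    def n_bins(self) -> int:
        return self.intensities.shape[1]

    def subset(
        self,
        groups: tuple[str, ...] | list[str] | None = None,
        timepoint: int | None = None,
        fluid: str | None = None,
    ) -> "SpectralDataset":
        """Return the sub-dataset matching the given metadata filters."""
        mask = pd.Series(True, index=self.metadata.index)
        if groups is not None:
            mask &= self.metadata["group"].isin(list(groups))
        if timepoint is not None:
            mask &= self.metadata["timepoint"].astype(int) == int(timepoint)
        if fluid is not None:
            mask &= self.metadata["fluid"] == fluid
        ids = self.metadata.index[mask]
        if len(ids) == 0:
            raise DatasetError(
                f"no samples match groups={groups} timepoint={timepoint} fluid={fluid}"
            )
        return SpectralDataset(
            self.intensities.loc[ids].copy(), self.metadata.loc[ids].copy()
        )

    def with_intensities(self, X: pd.DataFrame) -> "SpectralDataset":
        """Same metadata, new intensity matrix (e.g. after normalization)."""
        return SpectralDataset(X, self.metadata.copy())

    # -- I/O -----------------------------------------------------------

    def to_csv(self, matrix_path: str | Path, metadata_path: str | Path) -> None:
        self.intensities.to_csv(matrix_path, index_label="sample_id")
        self.metadata.to_csv(metadata_path, index_label="sample_id")

    @classmethod
    def from_csv(
        cls, matrix_path: str | Path, metadata_path: str | Path
    ) -> "SpectralDataset":
        X = pd.read_csv(matrix_path, index_col="sample_id")
        meta = pd.read_csv(metadata_path, index_col="sample_id")
        return cls(X, meta)


def read_dataset(matrix_path: str | Path, metadata_path: str | Path) -> SpectralDataset:
    """Read and validate a dataset from its two CSV files.

    The matrix CSV has a ``sample_id`` first column and one column per
    bin; the metadata CSV is keyed by ``sample_id`` with ``group``,
    ``timepoint`` and ``fluid`` columns.
    """
    return SpectralDataset.from_csv(matrix_path, metadata_path)


# -- covariates --------------------------------------------------------

COVARIATE_COLUMNS = (
    "iba1_density",
    "gfap_density",
    "mbp_loss_area",
    "nfh_loss_area",
    "nfl_serum",
    "nfl_csf",
)


@dataclass
class CovariateRecord:
    """Per-animal histology and neurofilament measurements.

    ``iba1_density`` and ``gfap_density`` are immunopositive-cell
    densities (cells/mm^2) for microglia/macrophages and astrocytes;
    ``mbp_loss_area`` / ``nfh_loss_area`` are demyelination and axonal
    loss areas (mm^2), zero by definition in unlesioned animals;
    ``nfl_serum`` / ``nfl_csf`` are neurofilament-light concentrations
    (pg/mL).
    """

    sample_id: str
    iba1_density: float
    gfap_density: float
    mbp_loss_area: float
    nfh_loss_area: float
    nfl_serum: float
    nfl_csf: float

    def __post_init__(self) -> None:
        for name in COVARIATE_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DatasetError(
                    f"covariate {name} for {self.sample_id} must be >= 0, got {v}"
                )


def covariates_to_frame(records: list[CovariateRecord]) -> pd.DataFrame:
    """Stack covariate records into a DataFrame indexed by sample id."""
    df = pd.DataFrame([vars(r) for r in records]).set_index("sample_id")
    return df[list(COVARIATE_COLUMNS)]


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a covariate CSV (sample_id key plus the six covariate columns)."""
    df = pd.read_csv(path, index_col="sample_id")
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(f"covariate table missing columns: {sorted(missing)}")
    # route every row through the record validator
    for sid, row in df.iterrows():
        CovariateRecord(sample_id=str(sid), **{c: float(row[c]) for c in COVARIATE_COLUMNS})
    return df[list(COVARIATE_COLUMNS)]
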