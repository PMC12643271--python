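"""Core domain types shared by every stage of the pipeline.

The universal expression carrier is a genes x observations matrix with an
explicit layer tag (``counts``, ``tpm`` or ``lognorm``); cell- and
sample-level metadata travel alongside it as typed containers that validate
the invariants downstream stages rely on (unique identifiers, finite
non-negative counts, TPM columns summing to one million, the three-level
tissue vocabulary PT / ECM / MBM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("counts", "tpm", "lognorm")
TISSUES = ("PT", "ECM", "MBM")

TPM_TOTAL = 1e6
TPM_RTOL = 1e-6


class MatrixError(ValueError):
    """Malformed expression matrix (bad layer, negative counts, ...)."""


class DuplicateIdError(MatrixError):
    """Duplicate gene or observation identifiers."""


class DimensionMismatchError(MatrixError):
    """Matrix shape inconsistent with its identifier vectors."""


@dataclass
class ExpressionMatrix:
    """Genes x observations expression matrix with a layer tag.

    Parameters
    ----------
    values
        DataFrame with genes as the index and observations (cells or bulk
        samples) as columns.
    layer
        One of ``counts``, ``tpm``, ``lognorm``.
    gene_lengths
        Optional per-gene transcript lengths in base pairs; required before
        TPM normalization. Must be positive and cover every gene.
    """

    values: pd.DataFrame
    layer: str = "counts"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.layer not in LAYERS:
            raise MatrixError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate observation ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise MatrixError("expression values must be finite")
        if self.layer in ("counts", "tpm") and arr.size and arr.min() < 0:
            raise MatrixError(f"{self.layer} layer must be non-negative")
        if self.layer == "tpm" and arr.size:
            colsum = arr.sum(axis=0)
            bad = ~np.isclose(colsum, TPM_TOTAL, rtol=TPM_RTOL)
            if bad.any():
                raise MatrixError(
                    f"tpm columns must sum to {TPM_TOTAL:g}; offending: "
                    f"{list(cols[bad][:5])}"
                )
        if self.gene_lengths is not None:
            self.gene_lengths = pd.Series(self.gene_lengths, dtype=float)
            missing = idx.difference(self.gene_lengths.index)
            if len(missing):
                raise MatrixError(f"gene_lengths missing for {list(missing[:5])}")
            self.gene_lengths = self.gene_lengths.reindex(idx)
            if (self.gene_lengths <= 0).any() or not np.isfinite(
                self.gene_lengths.to_numpy()
            ).all():
                raise MatrixError("gene_lengths must be positive and finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def obs_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_obs(self, obs: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(obs)], self.layer, self.gene_lengths)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        gl = self.gene_lengths
        if gl is not None:
            gl = gl.loc[list(genes)]
        return ExpressionMatrix(self.values.loc[list(genes)], self.layer, gl)

    def copy(self) -> "ExpressionMatrix":
        gl = None if self.gene_lengths is None else self.gene_lengths.copy()
        return ExpressionMatrix(self.values.copy(), self.layer, gl)


@dataclass
class CellAnnotation:
    """Per-cell labels: cell type, tissue compartment, cluster, malignancy.

    ``table`` is indexed by cell id with columns ``cell_type``, ``tissue``,
    ``cluster`` and ``is_malignant``. Tissues are restricted to the three
    compartments of the study design: primary tumor (PT), extracranial
    metastasis (ECM) and brain metastasis (MBM).
    """

    table: pd.DataFrame

    REQUIRED = ("cell_type", "tissue", "cluster", "is_malignant")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")
        if self.table.index.has_duplicates:
            raise DuplicateIdError("duplicate cell ids in annotation")
        bad = set(self.table["tissue"].unique()) - set(TISSUES)
        if bad:
            raise ValueError(f"tissue labels outside {TISSUES}: {sorted(bad)}")
        self.table = self.table.copy()
        self.table["is_malignant"] = self.table["is_malignant"].astype(bool)

    @property
    def cell_ids(self) -> pd.Index:
        return self.table.index

    def check_matches(self, m: ExpressionMatrix) -> None:
        """Require the annotation's cell set to equal the matrix's columns."""
        if set(self.cell_ids) != set(m.obs_ids):
            raise DimensionMismatchError(
                "annotation cell ids do not match matrix observation ids"
            )

    def aligned_to(self, m: ExpressionMatrix) -> "CellAnnotation":
        self.check_matches(m)
        return CellAnnotation(self.table.loc[m.obs_ids])


@dataclass
class GeneSignature:
    """A named gene set with optional per-gene weights (default 1)."""

    name: str
    genes: list[str]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DuplicateIdError(f"signature {self.name!r} has duplicate genes")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise ValueError(
                f"signature {self.name!r}: {len(self.weights)} weights for "
                f"{len(self.genes)} genes"
            )

    def weight_series(self) -> pd.Series:
        w = self.weights if self.weights is not None else [1.0] * len(self.genes)
        return pd.Series(w, index=self.genes, dtype=float)


@dataclass
class SurvivalRecord:
    """One sample's follow-up: time in days, death indicator, covariates."""

    sample_id: str
    time: float
    event: bool
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"{self.sample_id}: time must be finite and >= 0")
        self.event = bool(self.event)


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Survival records -> DataFrame indexed by sample_id (time, event, covariates)."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "time": float(r.time), "event": bool(r.event)}
        row.update(r.covariates)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["time", "event"]).rename_axis("sample_id")
    df = pd.DataFrame(rows).set_index("sample_id")
    if df.index.has_duplicates:
        raise DuplicateIdError("duplicate sample ids in survival records")
    return df


def frame_to_records(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Inverse of :func:`records_to_frame`."""
    covcols = [c for c in df.columns if c not in ("time", "event")]
    return [
        SurvivalRecord(
            sample_id=str(i),
            time=float(row["time"]),
            event=bool(row["event"]),
            covariates={c: row[c] for c in covcols},
        )
        for i, row in df.iterrows()
    ]


def as_survival_frame(records) -> pd.DataFrame:
    """Accept either a list of SurvivalRecord or a prepared DataFrame."""
    if isinstance(records, pd.DataFrame):
        for col in ("time", "event"):
            if col not in records.columns:
                raise ValueError(f"survival frame missing {col!r} column")
        return records
    return records_to_frame(records)
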