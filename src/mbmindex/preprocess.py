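"""QC filtering and normalization.

Cell-level QC mirrors the standard droplet workflow: cells are removed when
their mitochondrial count fraction exceeds 20% or when they express fewer
than 500 or more than 5,000 genes; the boundary values themselves are
retained (the exclusions are strict inequalities). Bulk cohorts are cleaned
by dropping labelled samples (e.g. "normal"), samples without survival data
and samples with overall survival below 30 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, MatrixError, as_survival_frame


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_mito: int
    removed_min_genes: int
    removed_max_genes: int


def qc_filter_cells(
    m: ExpressionMatrix,
    mito_gene_prefix: str = "MT-",
    max_mito_frac: float = 0.20,
    min_genes: int = 500,
    max_genes: int = 5000,
) -> tuple[ExpressionMatrix, QCReport]:
    """Keep cells with mito fraction <= ``max_mito_frac`` and a detected-gene
    count inside ``[min_genes, max_genes]`` (inclusive bounds retained).

    The report counts, per criterion, how many cells violated it; a cell can
    contribute to several counts.
    """
    if m.layer != "counts":
        raise MatrixError(f"qc_filter_cells requires the counts layer, got {m.layer!r}")
    arr = m.values.to_numpy()
    totals = arr.sum(axis=0)
    is_mito = np.asarray(m.gene_ids.str.startswith(mito_gene_prefix))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, arr[is_mito].sum(axis=0) / np.maximum(totals, 1), 0.0)
    n_detected = (arr > 0).sum(axis=0)

    fail_mito = mito_frac > max_mito_frac
    fail_min = n_detected < min_genes
    fail_max = n_detected > max_genes
    keep = ~(fail_mito | fail_min | fail_max)

    report = QCReport(
        n_input=m.shape[1],
        n_kept=int(keep.sum()),
        removed_mito=int(fail_mito.sum()),
        removed_min_genes=int(fail_min.sum()),
        removed_max_genes=int(fail_max.sum()),
    )
    if report.n_kept == 0:
        warnings.warn("QC filtering removed every cell", stacklevel=2)
    out = ExpressionMatrix(m.values.loc[:, keep], layer="counts", gene_lengths=m.gene_lengths)
    return out, report


def tpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts-per-million: counts -> reads-per-kilobase -> per-million scaling.

    Requires per-gene lengths on the matrix. Every output column sums to 1e6.
    """
    if m.layer != "counts":
        raise MatrixError(f"tpm_normalize requires the counts layer, got {m.layer!r}")
    if m.gene_lengths is None:
        raise MatrixError("tpm_normalize requires gene_lengths")
    lengths = m.gene_lengths.to_numpy(dtype=float)
    arr = m.values.to_numpy(dtype=float)
    rpk = arr / (lengths[:, None] / 1000.0)
    colsum = rpk.sum(axis=0)
    zero = colsum <= 0
    if zero.any():
        raise MatrixError(
            f"all-zero column(s) cannot be TPM-normalized: {list(m.obs_ids[zero][:5])}"
        )
    tpm = rpk / colsum * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=m.gene_ids, columns=m.obs_ids),
        layer="tpm",
        gene_lengths=m.gene_lengths,
    )


def log_normalize(m: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Per-cell depth normalization followed by log1p: ln(1 + sf * x / total)."""
    if m.layer != "counts":
        raise MatrixError(f"log_normalize requires the counts layer, got {m.layer!r}")
    arr = m.values.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        raise MatrixError(
            f"zero-total cell(s) cannot be log-normalized: {list(m.obs_ids[zero][:5])}"
        )
    out = np.log1p(scale_factor * arr / totals)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.obs_ids),
        layer="lognorm",
        gene_lengths=m.gene_lengths,
    )


@dataclass
class CohortFilterReport:
    n_input: int
    n_kept: int
    removed_by_label: int
    removed_missing_survival: int
    removed_short_os: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)


def filter_bulk_cohort(
    expr: ExpressionMatrix,
    surv,
    min_os_days: int = 30,
    drop_labels: set[str] = frozenset({"normal"}),
    sample_labels: Mapping[str, str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortFilterReport]:
    """Apply the bulk-cohort exclusion rules in order: designated labels
    (e.g. "normal"), missing survival, overall survival < ``min_os_days``
    (strict; a sample at exactly the cutoff is retained).

    ``sample_labels`` maps sample id -> designation; when omitted, a
    ``sample_type`` covariate column in the survival table is used if present.
    Returns expression and survival restricted to the same ordered sample set.
    """
    sdf = as_survival_frame(surv)
    samples = list(expr.obs_ids)
    labels: dict[str, str] = {}
    if sample_labels is not None:
        labels = {str(k): str(v) for k, v in sample_labels.items()}
    elif "sample_type" in sdf.columns:
        labels = sdf["sample_type"].astype(str).to_dict()

    by_label = [s for s in samples if labels.get(s) in drop_labels]
    rest = [s for s in samples if s not in set(by_label)]
    missing = [s for s in rest if s not in sdf.index]
    rest = [s for s in rest if s in sdf.index]
    short = [s for s in rest if sdf.loc[s, "time"] < min_os_days]
    kept = [s for s in rest if s not in set(short)]

    report = CohortFilterReport(
        n_input=len(samples),
        n_kept=len(kept),
        removed_by_label=len(by_label),
        removed_missing_survival=len(missing),
        removed_short_os=len(short),
        removed_ids={"label": by_label, "missing_survival": missing, "short_os": short},
    )
    if not kept:
        warnings.warn("cohort filtering removed every sample", stacklevel=2)
        return (
            ExpressionMatrix(expr.values.iloc[:, :0], expr.layer, expr.gene_lengths),
            sdf.iloc[:0],
            report,
        )
    return expr.subset_obs(kept), sdf.loc[kept], report
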