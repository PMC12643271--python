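"""Per-cell gene-program scoring and tissue-enrichment statistics.

``module_score`` reimplements the binned-control module-scoring scheme used
throughout single-cell work: genes are cut into equal-frequency bins by
their mean expression, each program gene draws control genes from its own
bin, and a cell's score is the program mean minus the pooled-control mean.
``roe`` computes the ratio of observed to expected cell counts for every
(cell type, tissue) pair under the independence model; a ratio above 1
marks tissue enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CellAnnotation, ExpressionMatrix, GeneSignature, MatrixError


def module_score(
    m: ExpressionMatrix,
    sig: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Program activity per cell: mean signature expression minus the mean
    of expression-bin-matched control genes.

    Control genes are sampled per signature gene from its equal-frequency
    mean-expression bin, excluding signature genes, without replacement
    unless the bin is smaller than ``n_ctrl``. Deterministic given ``seed``.
    Returns a Series indexed by cell id, named after the signature.
    """
    if m.layer != "lognorm":
        raise MatrixError(f"module_score expects the lognorm layer, got {m.layer!r}")
    if n_bins > m.shape[0]:
        raise ValueError(f"n_bins={n_bins} exceeds the {m.shape[0]} available genes")
    present = [g for g in sig.genes if g in m.gene_ids]
    missing = set(sig.genes) - set(present)
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is present in the matrix")
    if missing:
        warnings.warn(
            f"signature {sig.name!r}: dropping {len(missing)} absent gene(s)",
            stacklevel=2,
        )

    arr = m.values.to_numpy()
    gene_means = arr.mean(axis=1)
    # canonical ordering (mean, then gene id) so results do not depend on
    # the on-disk gene order
    ids = np.asarray(m.gene_ids, dtype=object)
    order = np.lexsort((ids, gene_means))
    bin_of = np.empty(m.shape[0], dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    sig_pos = np.array([gene_pos[g] for g in present])
    sig_set = set(sig_pos.tolist())
    pool_by_bin = {
        b: np.array(
            [i for i in order[bin_of[order] == b] if i not in sig_set], dtype=int
        )
        for b in range(n_bins)
    }

    def pool_for(b: int) -> np.ndarray:
        # widen to neighbouring bins if the signature exhausts this one
        for width in range(n_bins):
            lo, hi = max(0, b - width), min(n_bins - 1, b + width)
            pool = np.concatenate([pool_by_bin[k] for k in range(lo, hi + 1)])
            if len(pool):
                return pool
        raise ValueError(
            f"signature {sig.name!r}: no non-signature control genes available"
        )

    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for p in sig_pos:
        pool = pool_for(int(bin_of[p]))
        replace = len(pool) < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)
    scores = arr[sig_pos].mean(axis=0) - arr[ctrl].mean(axis=0)
    return pd.Series(scores, index=m.obs_ids, name=sig.name)


def score_functional_states(
    m: ExpressionMatrix,
    signatures: dict[str, GeneSignature],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score a set of programs (e.g. naive / activation-effector /
    exhaustion / cytotoxicity T-cell states) per cell; cells x programs."""
    cols = {
        name: module_score(m, sig, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        for name, sig in signatures.items()
    }
    return pd.DataFrame(cols, index=m.obs_ids)


@dataclass
class RoeTable:
    """Observed and expected cell counts per (cell type, tissue), their
    ratio, and the enrichment flag (ratio > 1). Ratios where the expected
    count is zero are reported as NaN."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    ratio: pd.DataFrame

    @property
    def enriched(self) -> pd.DataFrame:
        return self.ratio > 1

    def to_long(self) -> pd.DataFrame:
        out = pd.concat(
            {
                "observed": self.observed.stack(),
                "expected": self.expected.stack(),
                "ratio": self.ratio.stack(),
            },
            axis=1,
        )
        out.index.names = ["cell_type", "tissue"]
        return out.reset_index()


def roe(ann: CellAnnotation) -> RoeTable:
    """Ratio of observed to expected counts under cell_type x tissue
    independence: expected_ij = row_i * col_j / grand total."""
    if len(ann.table) == 0:
        raise ValueError("no cells to tabulate")
    observed = pd.crosstab(ann.table["cell_type"], ann.table["tissue"]).astype(float)
    row = observed.sum(axis=1).to_numpy()
    col = observed.sum(axis=0).to_numpy()
    grand = observed.to_numpy().sum()
    expected = pd.DataFrame(
        np.outer(row, col) / grand, index=observed.index, columns=observed.columns
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed / expected
    ratio = ratio.where(expected > 0)
    return RoeTable(observed=observed, expected=expected, ratio=ratio)
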