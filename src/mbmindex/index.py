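"""The MBM-Index: signature derivation, one-class logistic regression,
Spearman scoring, 0-1 scaling and stratification.

The index follows the stemness-index (OCLR) paradigm: a weight vector is
learned from positive-class observations only — here, cells of the
brain-metastasis-associated malignant subpopulation (MBMATC) — under an
elastic-net penalty, and each bulk sample is scored by the Spearman
correlation between the weight vector and the sample's expression over the
signature genes. Cohort correlations are linearly rescaled to [0, 1]; a
higher index means greater transcriptome-wide resemblance to the MBMATC
state, i.e. greater inferred brain-metastasis risk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .datatypes import CellAnnotation, ExpressionMatrix, GeneSignature, MatrixError


class SignatureDerivationError(ValueError):
    """No gene survives the differential-expression filters."""


def derive_signature(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    target_label: str,
    min_log2fc: float = 0.25,
    max_fdr: float = 0.05,
    min_frac: float = 0.10,
    name: str | None = None,
) -> GeneSignature:
    """Differential expression of the target malignant cluster against all
    other malignant cells: two-sided Wilcoxon rank-sum per gene,
    Benjamini-Hochberg FDR, Seurat-style log2 fold change of
    ``mean(expm1(x)) + 1``, plus a minimum detection fraction in the target.
    The returned signature is ranked by decreasing log2FC and carries the
    log2FC values as weights.
    """
    if m.layer != "lognorm":
        raise MatrixError(f"derive_signature expects the lognorm layer, got {m.layer!r}")
    ann = ann.aligned_to(m)
    tab = ann.table
    malignant = tab.index[tab["is_malignant"]]
    target = [c for c in malignant if tab.loc[c, "cluster"] == target_label]
    background = [c for c in malignant if tab.loc[c, "cluster"] != target_label]
    if not target or not background:
        raise ValueError(
            f"need non-empty target ({len(target)}) and background "
            f"({len(background)}) malignant cell sets"
        )

    X = m.values
    xt = X.loc[:, target].to_numpy()
    xb = X.loc[:, background].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes yield p=1, not a failure
        res = scipy.stats.mannwhitneyu(
            xt, xb, axis=1, alternative="two-sided", method="asymptotic"
        )
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    fdr = scipy.stats.false_discovery_control(pvals, method="bh")

    mean_t = np.expm1(xt).mean(axis=1) + 1.0
    mean_b = np.expm1(xb).mean(axis=1) + 1.0
    log2fc = np.log2(mean_t / mean_b)
    frac_t = (xt > 0).mean(axis=1)

    pass_fc = log2fc >= min_log2fc
    pass_fdr = fdr <= max_fdr
    pass_frac = frac_t >= min_frac
    keep = pass_fc & pass_fdr & pass_frac
    if not keep.any():
        raise SignatureDerivationError(
            "no gene passed the filters "
            f"(log2FC>={min_log2fc}: {int(pass_fc.sum())}, "
            f"FDR<={max_fdr}: {int(pass_fdr.sum())}, "
            f"detection>={min_frac}: {int(pass_frac.sum())})"
        )
    sel = pd.DataFrame(
        {"log2fc": log2fc[keep]}, index=m.gene_ids[keep]
    ).sort_values("log2fc", ascending=False)
    return GeneSignature(
        name=name or f"{target_label}_signature",
        genes=list(sel.index),
        weights=list(sel["log2fc"]),
    )


@dataclass
class OCLRModel:
    """One-class logistic regression model: per-gene weights plus the
    penalties, centering vector and convergence record of the fit."""

    gene_ids: list[str]
    w: np.ndarray
    lambda1: float
    lambda2: float
    n_train: int
    converged: bool
    final_objective: float
    n_iter: int
    centering: np.ndarray | None = None
    objective_history: list[float] = field(default_factory=list, repr=False)

    def weight_series(self) -> pd.Series:
        return pd.Series(self.w, index=self.gene_ids)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "w": [float(x) for x in self.w],
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "n_train": self.n_train,
            "converged": self.converged,
            "final_objective": self.final_objective,
            "n_iter": self.n_iter,
            "centering": None if self.centering is None else [float(x) for x in self.centering],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "OCLRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=d["gene_ids"],
            w=np.asarray(d["w"], dtype=float),
            lambda1=d["lambda1"],
            lambda2=d["lambda2"],
            n_train=d["n_train"],
            converged=d["converged"],
            final_objective=d["final_objective"],
            n_iter=d["n_iter"],
            centering=None if d["centering"] is None else np.asarray(d["centering"], dtype=float),
        )


def oclr_objective(
    w: np.ndarray, X: np.ndarray, lambda1: float, lambda2: float
) -> float:
    """J(w) = -(1/n) sum_i log sigma(w.x_i) + l1*||w||_1 + (l2/2)*||w||_2^2
    with X of shape (genes, observations)."""
    s = X.T @ w
    # -log sigma(s) = log(1 + exp(-s)), computed stably
    nll = np.logaddexp(0.0, -s).mean()
    return float(nll + lambda1 * np.abs(w).sum() + 0.5 * lambda2 * w @ w)


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def fit_oclr(
    train: ExpressionMatrix,
    lambda1: float = 0.0,
    lambda2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10000,
    center: bool = True,
    center_by: np.ndarray | pd.Series | None = None,
) -> OCLRModel:
    """Fit the one-class logistic objective by proximal gradient descent
    (soft-thresholding for the L1 term) with backtracking line search; the
    objective sequence is non-increasing by construction.

    ``center_by`` supplies an external per-gene centering vector — in the
    stemness-index workflow the gene means of the full reference population,
    so that the positive class retains a non-zero mean direction. When
    omitted and ``center`` is true, the training mean is used.
    """
    X = train.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise MatrixError("training matrix contains non-finite values")
    p, n = X.shape
    centering = None
    if center_by is not None:
        centering = (
            center_by.reindex(train.gene_ids).to_numpy(dtype=float)
            if isinstance(center_by, pd.Series)
            else np.asarray(center_by, dtype=float)
        )
        if centering.shape != (p,):
            raise ValueError("center_by must supply one value per gene")
    elif center:
        centering = X.mean(axis=1)
    if centering is not None:
        X = X - centering[:, None]

    w = np.zeros(p)
    step = 1.0
    history = [oclr_objective(w, X, lambda1, lambda2)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = X.T @ w
        # grad of smooth part: -(1/n) X sigma(-s) + lambda2 w
        grad = -(X @ scipy.special.expit(-s)) / n + lambda2 * w
        f_w = history[-1] - lambda1 * np.abs(w).sum()
        while True:
            w_new = _soft_threshold(w - step * grad, step * lambda1)
            delta = w_new - w
            f_new = oclr_objective(w_new, X, 0.0, lambda2)
            if f_new <= f_w + grad @ delta + (delta @ delta) / (2.0 * step) + 1e-15:
                break
            step *= 0.5
            if step < 1e-12:
                break
        obj = f_new + lambda1 * np.abs(w_new).sum()
        # guard: never accept an increase (floating point edge cases)
        if obj > history[-1]:
            break
        w = w_new
        history.append(obj)
        if abs(history[-2] - history[-1]) <= tol * max(1.0, abs(history[-2])):
            converged = True
            break
        step = min(step * 2.0, 1e6)  # allow the step to grow back

    if not converged:
        warnings.warn(f"OCLR did not converge in {it} iterations", stacklevel=2)
    return OCLRModel(
        gene_ids=list(train.gene_ids),
        w=w,
        lambda1=lambda1,
        lambda2=lambda2,
        n_train=n,
        converged=converged,
        final_objective=history[-1],
        n_iter=it,
        centering=centering,
        objective_history=history,
    )


def score_samples(model: OCLRModel, cohort: ExpressionMatrix) -> pd.DataFrame:
    """Spearman correlation between the model weights and each sample's
    expression over the shared signature genes (average ranks for ties).
    Returns a DataFrame indexed by sample id with a ``rho`` column."""
    shared = [g for g in model.gene_ids if g in cohort.gene_ids]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} signature genes found in the cohort; need >= 3"
        )
    if len(shared) < 0.5 * len(model.gene_ids):
        warnings.warn(
            f"only {len(shared)}/{len(model.gene_ids)} signature genes found in cohort",
            stacklevel=2,
        )
    w = model.weight_series().loc[shared].to_numpy()
    X = cohort.values.loc[shared].to_numpy(dtype=float)
    const = X.max(axis=0) == X.min(axis=0)
    if const.any():
        raise ValueError(
            "constant expression over signature genes; Spearman undefined for "
            f"sample(s) {list(cohort.obs_ids[const][:5])}"
        )
    rw = scipy.stats.rankdata(w)
    rX = scipy.stats.rankdata(X, axis=0)
    rw_c = rw - rw.mean()
    rX_c = rX - rX.mean(axis=0)
    rho = (rX_c.T @ rw_c) / (
        np.sqrt((rw_c @ rw_c)) * np.sqrt((rX_c**2).sum(axis=0))
    )
    return pd.DataFrame({"rho": rho}, index=pd.Index(cohort.obs_ids, name="sample_id"))


def scale_index(results: pd.DataFrame) -> pd.DataFrame:
    """Linear 0-1 rescaling of the cohort correlations: the minimum maps to
    0, the maximum to 1, ordering preserved."""
    rho = results["rho"].to_numpy(dtype=float)
    if len(rho) < 2:
        raise ValueError("need at least 2 samples to scale the index")
    lo, hi = rho.min(), rho.max()
    if hi == lo:
        raise ValueError("degenerate cohort: all correlations identical")
    out = results.copy()
    out["index"] = (rho - lo) / (hi - lo)
    return out


def stratify(results: pd.DataFrame, rule: str | tuple = "median") -> pd.DataFrame:
    """Assign high/low groups by a cutpoint on the scaled index.

    ``rule``: ``"median"``, ``("quantile", q)`` or ``("fixed", c)``.
    High = index strictly above the cutpoint; ties go to low.
    """
    if "index" not in results.columns:
        raise ValueError("scale_index must run before stratify")
    idx = results["index"].to_numpy(dtype=float)
    if rule == "median":
        cut = float(np.median(idx))
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "quantile":
        cut = float(np.quantile(idx, rule[1]))
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "fixed":
        cut = float(rule[1])
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    out = results.copy()
    out["group"] = np.where(idx > cut, "high", "low")
    if len(set(out["group"])) == 1:
        warnings.warn("stratification put every sample on one side", stacklevel=2)
    return out
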