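"""Drug-sensitivity imputation and the two-tiered candidate screen.

Sensitivity scores are IC50-like: lower means more sensitive. Imputation
fits one ridge regression per drug on standardized reference cell-line
expression and projects it onto the target cohort. The screen declares a
drug a candidate in an arm (cell-state contrast or high-vs-low index
contrast) when the target group shows log2 fold-change of mean score below
the threshold (default -0.1) AND a Mann-Whitney U p-value below 0.05; the
final set per arm intersects the hits across response databases.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import Ridge, RidgeCV

from .datatypes import ExpressionMatrix

DEFAULT_RIDGE_GRID = tuple(10.0**k for k in range(-2, 5))
EXACT_CUTOVER = 12  # combined sample size at or below which U is enumerated


@dataclass
class DrugSensitivity:
    """Samples x drugs sensitivity score matrix from one database."""

    database: str
    scores: pd.DataFrame
    provenance: str = "supplied"  # supplied | imputed | simulated

    def __post_init__(self) -> None:
        if self.scores.columns.has_duplicates:
            raise ValueError(f"duplicate drug ids in database {self.database!r}")
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError(f"non-finite sensitivity scores in {self.database!r}")


def impute_sensitivity(
    reference_expr: ExpressionMatrix,
    reference_response: pd.DataFrame,
    target_expr: ExpressionMatrix,
    ridge_lambda: float | None = None,
    database: str = "reference",
) -> DrugSensitivity:
    """Per-drug ridge regression of response on standardized shared-gene
    expression of the reference lines, predicted on identically
    standardized target samples.

    ``reference_response`` is lines x drugs; lines with missing response are
    dropped per drug (>= 3 required). When ``ridge_lambda`` is None the
    penalty is selected per drug by the leave-one-out criterion over a
    fixed grid. Drugs with constant response are skipped with a warning.
    """
    shared = [g for g in reference_expr.gene_ids if g in target_expr.gene_ids]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")
    R = reference_expr.values.loc[shared].to_numpy(dtype=float).T  # lines x genes
    T = target_expr.values.loc[shared].to_numpy(dtype=float).T  # samples x genes
    mu = R.mean(axis=0)
    sd = R.std(axis=0)
    sd[sd == 0] = 1.0
    Rz = (R - mu) / sd
    Tz = (T - mu) / sd

    lines = list(reference_expr.obs_ids)
    resp = reference_response.reindex(lines)
    preds: dict[str, np.ndarray] = {}
    for drug in resp.columns:
        y = resp[drug]
        ok = y.notna().to_numpy()
        if ok.sum() < 3:
            warnings.warn(f"drug {drug!r}: <3 reference responses, skipped", stacklevel=2)
            continue
        yv = y.to_numpy(dtype=float)[ok]
        if np.ptp(yv) == 0:
            warnings.warn(f"drug {drug!r}: constant response, skipped", stacklevel=2)
            continue
        if ridge_lambda is None:
            model = RidgeCV(alphas=DEFAULT_RIDGE_GRID)
        else:
            model = Ridge(alpha=ridge_lambda)
        model.fit(Rz[ok], yv)
        preds[drug] = model.predict(Tz)
    if not preds:
        raise ValueError("no drug could be imputed")
    out = pd.DataFrame(preds, index=target_expr.obs_ids)
    return DrugSensitivity(database=database, scores=out, provenance="imputed")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a, b) pairs with a > b, ties counting 1/2."""
    return float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())


def mann_whitney_u(a, b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Exact p by full enumeration of all group assignments of the pooled
    values when the combined size is at most 12 (or ``mode="exact"``);
    otherwise a tie-corrected normal approximation with continuity
    correction. Two identical multisets (all values tied) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    na, nb = len(a), len(b)
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return u_obs, 1.0

    exact = mode == "exact" or (mode == "auto" and na + nb <= EXACT_CUTOVER)
    mu = na * nb / 2.0
    if exact:
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        idx = range(na + nb)
        for comb in itertools.combinations(idx, na):
            sel = np.zeros(na + nb, dtype=bool)
            sel[list(comb)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total

    n = na + nb
    ranks = scipy.stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(scipy.stats.norm.sf(max(z, 0.0))))
    return u_obs, p


@dataclass
class DrugScreenTable:
    """Long-format per-(database, arm, drug) screen results plus the
    per-arm cross-database candidate intersections."""

    table: pd.DataFrame
    candidates: dict[str, list[str]] = field(default_factory=dict)
    fc_threshold: float = -0.1
    p_threshold: float = 0.05


def two_tier_screen(
    sens_by_db: dict[str, DrugSensitivity],
    arm_labels: dict[str, pd.Series],
    fc_threshold: float = -0.1,
    p_threshold: float = 0.05,
    log2fc_stat: str = "mean",
) -> DrugScreenTable:
    """Two-tiered drug screen with cross-database intersection.

    ``arm_labels`` maps an arm name (e.g. "mbmatc" for the cell-state
    contrast, "index" for high-vs-low patients) to a boolean Series over
    sample ids, True on the high-risk (target) side. Per database, arm and
    drug: log2FC = log2(stat(target scores) / stat(comparator scores)) and a
    two-sided Mann-Whitney test; a drug passes when log2FC < ``fc_threshold``
    and p < ``p_threshold``. Per arm, candidates are the drugs passing in
    every database.
    """
    if log2fc_stat not in ("mean", "median"):
        raise ValueError("log2fc_stat must be 'mean' or 'median'")
    stat = np.mean if log2fc_stat == "mean" else np.median
    rows = []
    for db, sens in sens_by_db.items():
        for arm, labels in arm_labels.items():
            lab = labels.reindex(sens.scores.index)
            if lab.isna().any():
                raise ValueError(f"arm {arm!r}: missing labels for database {db!r}")
            lab = lab.astype(bool)
            if lab.sum() < 2 or (~lab).sum() < 2:
                raise ValueError(f"arm {arm!r}: need >= 2 samples on each side")
            tgt_all = sens.scores.loc[lab].to_numpy(dtype=float)
            cmp_all = sens.scores.loc[~lab].to_numpy(dtype=float)
            for j, drug in enumerate(sens.scores.columns):
                t, c = tgt_all[:, j], cmp_all[:, j]
                mt, mc = float(stat(t)), float(stat(c))
                if mt <= 0 or mc <= 0:
                    raise ValueError(
                        f"drug {drug!r}: non-positive group {log2fc_stat} — "
                        "log2 fold-change undefined"
                    )
                log2fc = math.log2(mt / mc)
                u, p = mann_whitney_u(t, c, mode="auto")
                rows.append(
                    {
                        "database": db,
                        "arm": arm,
                        "drug": drug,
                        "log2fc": log2fc,
                        "U": u,
                        "p": p,
                        "passed": (log2fc < fc_threshold) and (p < p_threshold),
                    }
                )
    table = pd.DataFrame(rows)
    candidates: dict[str, list[str]] = {}
    dbs = list(sens_by_db)
    for arm in arm_labels:
        per_db = [
            set(
                table.loc[
                    (table["database"] == db) & (table["arm"] == arm) & table["passed"],
                    "drug",
                ]
            )
            for db in dbs
        ]
        candidates[arm] = sorted(set.intersection(*per_db)) if per_db else []
    table["intersection"] = [
        row["drug"] in candidates[row["arm"]] for _, row in table.iterrows()
    ]
    return DrugScreenTable(
        table=table,
        candidates=candidates,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
    )


def index_sensitivity_correlation(
    sens: DrugSensitivity, index: pd.DataFrame, drug: str
) -> tuple[float, float]:
    """Spearman correlation between one drug's sensitivity scores and the
    MBM-Index over paired samples; exact permutation p for n <= 9, the
    t approximation otherwise. A negative rho means higher-index samples
    are predicted more sensitive."""
    if drug not in sens.scores.columns:
        raise ValueError(f"unknown drug {drug!r}")
    shared = [s for s in index.index if s in sens.scores.index]
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} paired samples; need >= 5")
    x = sens.scores.loc[shared, drug].to_numpy(dtype=float)
    y = index.loc[shared, "index"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    n = len(shared)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        ry_c = ry - ry.mean()
        denom = math.sqrt(float((rx - rx.mean()) @ (rx - rx.mean())) * float(ry_c @ ry_c))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float((rx[list(perm)] - rx.mean()) @ ry_c) / denom
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)
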