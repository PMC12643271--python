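"""Survival analysis over index groups and clinical covariates.

Kaplan-Meier curves and Cox proportional-hazards fits are delegated to
lifelines (Efron tie handling, Wald confidence intervals); the two-group
log-rank statistic is additionally implemented here directly from the
observed-minus-expected construction with hypergeometric variance, so it
can serve as its own reference implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter

from .datatypes import as_survival_frame


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def km_estimate(records, groups: pd.Series | dict) -> list[KMCurve]:
    """Kaplan-Meier estimate per group. ``groups`` maps sample id -> label.
    Censored times reduce the risk set without a probability step."""
    df = as_survival_frame(records)
    if df.empty:
        raise ValueError("no survival records")
    g = pd.Series(groups).reindex(df.index)
    if g.isna().any():
        raise ValueError("every sample needs a group label")
    curves = []
    for label in sorted(g.unique()):
        sub = df.loc[g == label]
        if sub.empty:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(int))
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
        curves.append(KMCurve(group=str(label), times=times, survival=surv, at_risk=at_risk))
    return curves


def logrank_test(records, groups: pd.Series | dict) -> tuple[float, float]:
    """Two-group log-rank test, implemented in-module.

    At each distinct event time the observed events in group 1 are compared
    with the expectation ``d * n1 / n`` under the null, with hypergeometric
    variance ``d (n1/n)(n2/n)(n-d)/(n-1)``; the chi-square statistic on one
    degree of freedom gives the p-value.
    """
    df = as_survival_frame(records)
    g = pd.Series(groups).reindex(df.index)
    if g.isna().any():
        raise ValueError("every sample needs a group label")
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    in1 = (g == labels[0]).to_numpy()

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & in1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class CoxResult:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    model: str  # univariate | multivariate
    ok: bool = True
    note: str = ""


def _encode(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """One-hot encode categorical covariates with the first level as the
    reference; numeric terms pass through."""
    cols = {}
    for t in terms:
        if t not in df.columns:
            raise ValueError(f"unknown covariate {t!r}")
        col = df[t]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols[t] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for lv in levels[1:]:
                cols[f"{t}[{lv}]"] = (col.astype(str) == lv).astype(float)
    out = pd.DataFrame(cols, index=df.index)
    return out


def cox_fit(records, terms: list[str], model: str = "univariate") -> list[CoxResult]:
    """Cox proportional-hazards regression (Efron ties, Wald CIs).

    ``model="univariate"`` fits each term on its own; ``"multivariate"``
    fits them jointly. Rank-deficient designs and non-convergent fits are
    returned as flagged results rather than raised.
    """
    df = as_survival_frame(records)
    if model not in ("univariate", "multivariate"):
        raise ValueError(f"unknown model {model!r}")
    term_sets = [[t] for t in terms] if model == "univariate" else [list(terms)]
    results: list[CoxResult] = []
    for tset in term_sets:
        X = _encode(df, tset)
        bad = [c for c in X.columns if X[c].nunique() <= 1]
        dup = X.T.duplicated()
        if bad or dup.any():
            for c in X.columns:
                results.append(
                    CoxResult(c, np.nan, np.nan, np.nan, np.nan, np.nan, model,
                              ok=False, note="constant or duplicated covariate")
                )
            continue
        data = pd.concat([df[["time", "event"]].astype(float), X], axis=1)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(data, duration_col="time", event_col="event")
        except Exception as exc:
            for c in X.columns:
                results.append(
                    CoxResult(c, np.nan, np.nan, np.nan, np.nan, np.nan, model,
                              ok=False, note=f"fit failed: {exc}")
                )
            continue
        summ = cph.summary
        for c in X.columns:
            row = summ.loc[c]
            results.append(
                CoxResult(
                    term=c,
                    hr=float(row["exp(coef)"]),
                    ci_low=float(np.exp(row["coef lower 95%"])),
                    ci_high=float(np.exp(row["coef upper 95%"])),
                    p=float(row["p"]),
                    coef=float(row["coef"]),
                    model=model,
                )
            )
    return results


def cox_results_frame(results: list[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "HR": r.hr,
                "CI_low": r.ci_low,
                "CI_high": r.ci_high,
                "p": r.p,
                "coef": r.coef,
                "model": r.model,
                "ok": r.ok,
                "note": r.note,
            }
            for r in results
        ]
    )
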