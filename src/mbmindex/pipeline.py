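"""Config-driven end-to-end runs over the synthetic cohort.

A single YAML (or dict) config drives: simulation -> QC -> normalization ->
signature derivation -> OCLR fit -> cohort scoring and stratification ->
module scores and tissue enrichment -> survival analysis -> drug screen.
Every artifact is written as plain text under the output directory and
listed, with its SHA-256, in ``manifest.json``; rerunning with the same
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .datatypes import ExpressionMatrix
from .drugs import index_sensitivity_correlation, two_tier_screen
from .index import derive_signature, fit_oclr, scale_index, score_samples, stratify
from .preprocess import filter_bulk_cohort, log_normalize, qc_filter_cells, tpm_normalize
from .scoring import module_score, roe
from .simulate import (
    MBMATC_CLUSTER,
    SimulationConfig,
    simulate_bulk_cohort,
    simulate_cells,
    simulate_drug_response,
)
from .survival import cox_fit, cox_results_frame, km_estimate, logrank_test

log = logging.getLogger("mbmindex")


class ConfigError(ValueError):
    """Config fails validation (distinct from a YAML parse failure)."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        # demo-scale cohort; SimulationConfig defaults apply to anything unset
        "n_genes": 1200,
        "cell_counts": {
            "melanoma": {"PT": 150, "ECM": 150, "MBM": 150},
            "tcell": {"PT": 100, "ECM": 40, "MBM": 60},
            "treg": {"PT": 20, "ECM": 30, "MBM": 60},
            "macrophage": {"PT": 10, "ECM": 40, "MBM": 80},
        },
        "n_signature_genes": 80,
        "n_bulk_samples": 120,
    },
    "qc": {
        "mito_gene_prefix": "MT-",
        "max_mito_frac": 0.20,
        "min_genes": 200,
        "max_genes": 5000,
    },
    "cohort_filter": {"min_os_days": 30, "drop_labels": ["normal"]},
    "signature": {
        "target_label": MBMATC_CLUSTER,
        "min_log2fc": 0.25,
        "max_fdr": 0.05,
        "min_frac": 0.10,
    },
    "oclr": {"lambda1": 0.0, "lambda2": 1.0, "tol": 1e-6, "max_iter": 10000,
             "max_train_cells": 2000},
    "stratify": {"rule": "median", "value": None},
    "module_score": {"n_bins": 24, "n_ctrl": 100},
    "screen": {"fc_threshold": -0.1, "p_threshold": 0.05, "log2fc_stat": "mean"},
    "stages": {"survival": True, "drug_screen": True, "cell_scoring": True},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict) and k != "cell_counts":
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path) -> dict:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config parse failure: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return _deep_merge(DEFAULT_CONFIG, raw)


def validate_config(cfg: dict | str | Path) -> list[str]:
    """Return a list of violations (empty = valid). Never mutates."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    errs: list[str] = []
    if not isinstance(cfg.get("seed"), int):
        errs.append("seed: must be an integer")
    qc = cfg.get("qc", {})
    if not (0 < qc.get("max_mito_frac", 0.2) <= 1):
        errs.append("qc.max_mito_frac: must lie in (0, 1]")
    if qc.get("min_genes", 0) < 0 or qc.get("max_genes", 1) < qc.get("min_genes", 0):
        errs.append("qc.min_genes/max_genes: need 0 <= min <= max")
    try:
        SimulationConfig(seed=cfg.get("seed", 0), **cfg.get("simulate", {})).validate()
    except (TypeError, ValueError) as exc:
        errs.append(f"simulate: {exc}")
    sig = cfg.get("signature", {})
    if not (0 < sig.get("max_fdr", 0.05) <= 1):
        errs.append("signature.max_fdr: must lie in (0, 1]")
    if not (0 <= sig.get("min_frac", 0.1) <= 1):
        errs.append("signature.min_frac: must lie in [0, 1]")
    oclr = cfg.get("oclr", {})
    if oclr.get("lambda1", 0) < 0 or oclr.get("lambda2", 0) < 0:
        errs.append("oclr.lambda1/lambda2: penalties must be >= 0")
    strat = cfg.get("stratify", {})
    if strat.get("rule") not in ("median", "quantile", "fixed"):
        errs.append("stratify.rule: must be median, quantile or fixed")
    elif strat["rule"] in ("quantile", "fixed"):
        v = strat.get("value")
        if v is None or not (0 <= float(v) <= 1):
            errs.append("stratify.value: required in [0, 1] for quantile/fixed rules")
    screen = cfg.get("screen", {})
    if not (0 < screen.get("p_threshold", 0.05) <= 1):
        errs.append("screen.p_threshold: must lie in (0, 1]")
    if screen.get("fc_threshold", -0.1) >= 0:
        errs.append(
            "screen.fc_threshold: a non-negative threshold would select "
            "resistance, not sensitization"
        )
    if screen.get("log2fc_stat", "mean") not in ("mean", "median"):
        errs.append("screen.log2fc_stat: must be mean or median")
    if cfg.get("cohort_filter", {}).get("min_os_days", 30) < 0:
        errs.append("cohort_filter.min_os_days: must be >= 0")
    return errs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _strat_rule(cfg: dict):
    rule = cfg["stratify"]["rule"]
    if rule == "median":
        return "median"
    return (rule, float(cfg["stratify"]["value"]))


def run_pipeline(cfg: dict | str | Path, outdir: str | Path) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    else:
        cfg = _deep_merge(DEFAULT_CONFIG, cfg)
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = str(path.relative_to(outdir))

    # --- simulate -----------------------------------------------------
    sim_cfg = SimulationConfig(seed=cfg["seed"], **cfg["simulate"])
    log.info("simulate: seed=%d genes=%d", sim_cfg.seed, sim_cfg.n_genes)
    cells, ann, truth = simulate_cells(sim_cfg)
    bulk, surv, truth = simulate_bulk_cohort(sim_cfg, truth)
    mio.write_expression(cells, outdir / "cells", "mtx_triplet")
    emit("cells_matrix", outdir / "cells" / "matrix.mtx")
    mio.write_annotation(ann, outdir / "cell_annotation.tsv")
    emit("cell_annotation", outdir / "cell_annotation.tsv")
    mio.write_expression(bulk, outdir / "bulk_expression.tsv", "dense_tsv")
    emit("bulk_expression", outdir / "bulk_expression.tsv")
    mio.write_gene_lengths(bulk.gene_lengths, outdir / "gene_lengths.tsv")
    emit("gene_lengths", outdir / "gene_lengths.tsv")
    mio.write_survival(surv, outdir / "survival.csv")
    emit("survival_table", outdir / "survival.csv")
    truth.to_json(outdir / "truth.json")
    emit("truth", outdir / "truth.json")

    # --- QC + normalization ------------------------------------------
    qc = cfg["qc"]
    cells_f, qc_report = qc_filter_cells(
        cells,
        mito_gene_prefix=qc["mito_gene_prefix"],
        max_mito_frac=qc["max_mito_frac"],
        min_genes=qc["min_genes"],
        max_genes=qc["max_genes"],
    )
    ann_f = type(ann)(ann.table.loc[cells_f.obs_ids])
    log.info("qc: kept %d/%d cells", qc_report.n_kept, qc_report.n_input)
    lognorm = log_normalize(cells_f)

    bulk_f, surv_f, cohort_report = filter_bulk_cohort(
        bulk,
        surv,
        min_os_days=cfg["cohort_filter"]["min_os_days"],
        drop_labels=set(cfg["cohort_filter"]["drop_labels"]),
    )
    tpm = tpm_normalize(bulk_f)

    # --- signature + OCLR + index ------------------------------------
    sigp = cfg["signature"]
    signature = derive_signature(
        lognorm,
        ann_f,
        target_label=sigp["target_label"],
        min_log2fc=sigp["min_log2fc"],
        max_fdr=sigp["max_fdr"],
        min_frac=sigp["min_frac"],
    )
    mio.write_gmt([signature], outdir / "signature.gmt")
    emit("signature", outdir / "signature.gmt")

    malignant = ann_f.table.index[ann_f.table["is_malignant"]]
    target_cells = [
        c for c in malignant if ann_f.table.loc[c, "cluster"] == sigp["target_label"]
    ]
    max_train = int(cfg["oclr"]["max_train_cells"])
    if len(target_cells) > max_train:
        rng = np.random.default_rng(cfg["seed"])
        target_cells = list(
            np.array(target_cells)[rng.choice(len(target_cells), max_train, replace=False)]
        )
    train = lognorm.subset_genes(signature.genes).subset_obs(target_cells)
    reference_mean = lognorm.subset_genes(signature.genes).values.loc[:, malignant].mean(axis=1)
    model = fit_oclr(
        train,
        lambda1=cfg["oclr"]["lambda1"],
        lambda2=cfg["oclr"]["lambda2"],
        tol=cfg["oclr"]["tol"],
        max_iter=cfg["oclr"]["max_iter"],
        center_by=reference_mean,
    )
    model.to_json(outdir / "oclr_model.json")
    emit("oclr_model", outdir / "oclr_model.json")

    results = stratify(scale_index(score_samples(model, tpm)), _strat_rule(cfg))
    with open(outdir / "index.csv", "w", newline="\n") as fh:
        results.to_csv(fh, lineterminator="\n", float_format="%.10g")
    emit("index", outdir / "index.csv")

    # --- cell scoring -------------------------------------------------
    if cfg["stages"]["cell_scoring"]:
        ms = module_score(
            lognorm,
            signature,
            n_bins=cfg["module_score"]["n_bins"],
            n_ctrl=cfg["module_score"]["n_ctrl"],
            seed=cfg["seed"],
        )
        with open(outdir / "module_scores.tsv", "w", newline="\n") as fh:
            ms.rename("score").rename_axis("cell_id").to_csv(
                fh, sep="\t", lineterminator="\n", float_format="%.10g"
            )
        emit("module_scores", outdir / "module_scores.tsv")
        roe_table = roe(ann_f)
        with open(outdir / "roe.tsv", "w", newline="\n") as fh:
            roe_table.to_long().to_csv(
                fh, sep="\t", index=False, lineterminator="\n", float_format="%.10g"
            )
        emit("roe", outdir / "roe.tsv")

    # --- survival ------------------------------------------------------
    if cfg["stages"]["survival"]:
        groups = results.loc[surv_f.index, "group"]
        curves = km_estimate(surv_f, groups)
        km_rows = [
            {"group": c.group, "time": t, "survival": s, "at_risk": r}
            for c in curves
            for t, s, r in zip(c.times, c.survival, c.at_risk)
        ]
        with open(outdir / "km_curves.tsv", "w", newline="\n") as fh:
            pd.DataFrame(km_rows).to_csv(
                fh, sep="\t", index=False, lineterminator="\n", float_format="%.10g"
            )
        emit("km_curves", outdir / "km_curves.tsv")
        chi2, p = logrank_test(surv_f, groups)
        surv_aug = surv_f.copy()
        surv_aug["high_index"] = (groups == "high").astype(float)
        cox = cox_results_frame(cox_fit(surv_aug, ["high_index"], model="univariate"))
        with open(outdir / "cox.csv", "w", newline="\n") as fh:
            cox.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")
        emit("cox", outdir / "cox.csv")
        (outdir / "survival_tests.json").write_text(
            json.dumps({"logrank_chi2": chi2, "logrank_p": p}, indent=1, sort_keys=True)
        )
        emit("survival_tests", outdir / "survival_tests.json")

    # --- drug screen ---------------------------------------------------
    screen_summary = None
    if cfg["stages"]["drug_screen"]:
        tables, truth = simulate_drug_response(sim_cfg, truth)
        for db, sens in tables.items():
            mio.write_sensitivity(sens.scores, outdir / f"sensitivity_{db}.tsv")
            emit(f"sensitivity_{db}", outdir / f"sensitivity_{db}.tsv")
        # arm 1: the cell-state contrast (known state labels stand in for the
        # upstream annotation); arm 2: high- vs low-index patients; both
        # restricted to the filtered, scored cohort
        cohort = list(results.index)
        for db in tables:
            tables[db].scores = tables[db].scores.loc[cohort]
        f = truth.f_s.loc[cohort]
        arms = {
            "cell_state": pd.Series(f > f.median(), index=f.index),
            "index": results["group"].eq("high"),
        }
        screen = two_tier_screen(
            tables,
            arms,
            fc_threshold=cfg["screen"]["fc_threshold"],
            p_threshold=cfg["screen"]["p_threshold"],
            log2fc_stat=cfg["screen"]["log2fc_stat"],
        )
        with open(outdir / "drug_screen.csv", "w", newline="\n") as fh:
            screen.table.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")
        emit("drug_screen", outdir / "drug_screen.csv")
        final = sorted(set(screen.candidates.get("cell_state", []))
                       & set(screen.candidates.get("index", [])))
        corr = {
            d: dict(
                zip(("rho", "p"), index_sensitivity_correlation(tables["ctrp"], results, d))
            )
            for d in final
        }
        screen_summary = {
            "candidates_per_arm": screen.candidates,
            "final_candidates": final,
            "index_correlation_ctrp": corr,
        }
        (outdir / "screen_summary.json").write_text(
            json.dumps(screen_summary, indent=1, sort_keys=True)
        )
        emit("screen_summary", outdir / "screen_summary.json")

    manifest = {
        "config": cfg,
        "reports": {
            "qc": qc_report.__dict__,
            "cohort_filter": {
                k: v
                for k, v in cohort_report.__dict__.items()
                if k != "removed_ids"
            },
            "oclr": {
                "converged": model.converged,
                "n_iter": model.n_iter,
                "final_objective": model.final_objective,
                "n_signature_genes": len(model.gene_ids),
            },
        },
        "artifacts": {
            name: {"path": rel, "sha256": _sha256(outdir / rel)}
            for name, rel in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
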