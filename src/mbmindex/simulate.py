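"""Synthetic single-cell, bulk, survival and drug-response cohorts.

The generator reproduces the statistical structure the downstream analysis
assumes, with recorded ground truth, so the whole pipeline is testable
without any external download:

* single cells: negative-binomial counts with log-normal gene-level mean
  heterogeneity and cell-type-specific profiles; one malignant
  subpopulation ("MBMATC", the brain-metastasis-associated tumor-cell
  state) carries a planted signature whose genes are up-shifted by
  heterogeneous per-gene log2 effects (mean = ``signature_log2_effect``);
  tissue labels (PT / ECM / MBM) follow the configured per-tissue cell
  counts, so tissue enrichment has a known truth;
* bulk samples: convex mixtures of the cluster mean profiles with a latent
  MBMATC fraction ``f_s ~ Beta(a, b)`` and multiplicative log-normal noise;
* survival: exponential event times with hazard
  ``baseline_hazard * exp(hazard_beta * f_s)`` and independent exponential
  censoring;
* drug response: two database-like tables with shared effect structure and
  independent noise; effective drugs have score
  ``a_d - drug_effect_slope * f_s + noise`` (lower = more sensitive), null
  drugs have zero slope.

All randomness flows from one seed through fixed per-stage sub-streams, so
stages can be regenerated independently and runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CellAnnotation, ExpressionMatrix, GeneSignature
from .drugs import DrugSensitivity

MALIGNANT_TYPE = "melanoma"
MBMATC_CLUSTER = "MBMATC"

# fixed sub-stream indices: stages can be regenerated independently
_STREAM_CELLS = 0
_STREAM_BULK = 1
_STREAM_DRUGS = 2
_STREAM_LENGTHS = 3


def default_cell_counts() -> dict[str, dict[str, int]]:
    """Per-type, per-tissue cell counts. The Treg-like compartment is
    over-represented in MBM (and T cells depleted relative to PT), mirroring
    the immunosuppressive remodeling the enrichment statistic should detect.
    """
    return {
        "melanoma": {"PT": 400, "ECM": 400, "MBM": 400},
        "tcell": {"PT": 300, "ECM": 100, "MBM": 150},
        "treg": {"PT": 40, "ECM": 60, "MBM": 150},
        "macrophage": {"PT": 20, "ECM": 100, "MBM": 200},
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults chosen once to emulate the
    study design (three tissue compartments, a planted malignant
    subpopulation, a 200-sample bulk cohort with survival follow-up, and a
    50-drug screen with 5 truly coupled agents)."""

    seed: int = 0
    n_genes: int = 2000
    n_mito_genes: int = 13
    cell_counts: dict[str, dict[str, int]] = field(default_factory=default_cell_counts)
    mbmatc_frac: float = 0.3
    n_signature_genes: int = 100
    signature_log2_effect: float = 2.0
    nb_dispersion: float = 0.5
    signature_min_mean: float = 0.5
    signature_max_mean: float = 3.0
    baseline_log_mean: float = float(np.log(0.5))
    baseline_log_sd: float = 1.2
    type_profile_log_sd: float = 0.7
    n_qc_fail_cells: int = 0
    n_bulk_samples: int = 200
    fraction_beta: tuple[float, float] = (2.0, 3.0)
    bulk_noise_sd: float = 0.5
    hazard_beta: float = 2.0
    baseline_hazard: float = 1e-3
    censor_rate: float = 5e-4
    n_drugs: int = 50
    n_effective_drugs: int = 5
    drug_effect_slope: float = 0.3
    drug_noise_sd: float = 0.1
    gene_length_range: tuple[float, float] = (500.0, 10000.0)

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_mito_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.n_signature_genes > self.n_genes - self.n_mito_genes:
            raise ValueError("more signature genes than available genes")
        if not (0 <= self.mbmatc_frac <= 1):
            raise ValueError("mbmatc_frac must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if any(a <= 0 for a in self.fraction_beta):
            raise ValueError("fraction Beta parameters must be positive")
        if MALIGNANT_TYPE not in self.cell_counts:
            raise ValueError(f"cell_counts must include the {MALIGNANT_TYPE!r} type")
        for t, per_tissue in self.cell_counts.items():
            if any(n < 0 for n in per_tissue.values()):
                raise ValueError(f"negative cell count for type {t!r}")
        if self.n_effective_drugs > self.n_drugs:
            raise ValueError("n_effective_drugs exceeds n_drugs")
        if self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise ValueError("hazard parameters out of range")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )


@dataclass
class SyntheticTruth:
    """Ground-truth record written alongside every simulated dataset."""

    config: SimulationConfig
    planted_signature: GeneSignature
    signature_effects_log2: pd.Series
    cluster_profiles: pd.DataFrame  # expected NB mean, genes x clusters
    cell_labels: pd.DataFrame | None = None
    f_s: pd.Series | None = None
    effective_drug_ids: list[str] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "planted_signature": self.planted_signature.genes,
            "signature_effects_log2": self.signature_effects_log2.to_dict(),
            "f_s": None if self.f_s is None else self.f_s.to_dict(),
            "effective_drug_ids": self.effective_drug_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gene_ids(cfg: SimulationConfig) -> list[str]:
    mito = [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
    rest = [f"g{i:05d}" for i in range(cfg.n_genes - cfg.n_mito_genes)]
    return mito + rest


def gene_lengths(cfg: SimulationConfig) -> pd.Series:
    rng = cfg.rng(_STREAM_LENGTHS)
    lo, hi = cfg.gene_length_range
    return pd.Series(rng.uniform(lo, hi, cfg.n_genes), index=_gene_ids(cfg))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # NB2 parameterization: var = mu + dispersion * mu^2
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_cells(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, SyntheticTruth]:
    """Simulate the single-cell compartment and its ground truth."""
    cfg.validate()
    rng = cfg.rng(_STREAM_CELLS)
    genes = _gene_ids(cfg)
    g = cfg.n_genes

    base_log = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, g)
    type_log = {
        t: base_log + rng.normal(0.0, cfg.type_profile_log_sd, g)
        for t in cfg.cell_counts
    }

    # planted signature: drawn from genes expressed in the malignant
    # compartment (a marker of an undetectable gene is a contradiction),
    # with heterogeneous per-gene log2 effects whose mean is the configured
    # effect and whose floor keeps every planted gene genuinely shifted (a
    # uniform shift would leave within-signature ranks unchanged and carry
    # no rank-correlation signal)
    non_mito = np.arange(cfg.n_mito_genes, g)
    mal_mean = np.exp(type_log[MALIGNANT_TYPE])
    in_band = (mal_mean[non_mito] >= cfg.signature_min_mean) & (
        mal_mean[non_mito] <= cfg.signature_max_mean
    )
    eligible = non_mito[in_band]
    if len(eligible) < cfg.n_signature_genes:
        # fall back to the genes closest to the band's midpoint
        mid = 0.5 * (cfg.signature_min_mean + cfg.signature_max_mean)
        order = non_mito[np.argsort(np.abs(mal_mean[non_mito] - mid), kind="stable")]
        eligible = order[: cfg.n_signature_genes]
    sig_idx = np.sort(rng.choice(eligible, cfg.n_signature_genes, replace=False))
    if cfg.signature_log2_effect > 0:
        floor = min(0.5, 0.25 * cfg.signature_log2_effect)
        effects = rng.uniform(
            floor, 2.0 * cfg.signature_log2_effect - floor, cfg.n_signature_genes
        )
    else:
        effects = np.zeros(cfg.n_signature_genes)
    sig_genes = [genes[i] for i in sig_idx]
    effects_ser = pd.Series(effects, index=sig_genes)

    mbmatc_log = type_log[MALIGNANT_TYPE].copy()
    mbmatc_log[sig_idx] += effects * np.log(2.0)

    cluster_log = {
        (t if t != MALIGNANT_TYPE else MALIGNANT_TYPE): v for t, v in type_log.items()
    }
    cluster_log[MBMATC_CLUSTER] = mbmatc_log
    profiles = pd.DataFrame(
        {c: np.exp(v) for c, v in cluster_log.items()}, index=genes
    )

    cell_type_l, tissue_l, cluster_l, counts_cols = [], [], [], []
    for t, per_tissue in cfg.cell_counts.items():
        for tissue in ("PT", "ECM", "MBM"):
            n_cells = int(per_tissue.get(tissue, 0))
            if n_cells == 0:
                continue
            if t == MALIGNANT_TYPE and cfg.mbmatc_frac > 0:
                is_mbmatc = rng.random(n_cells) < cfg.mbmatc_frac
            else:
                is_mbmatc = np.zeros(n_cells, dtype=bool)
            mu = np.where(
                is_mbmatc[None, :],
                np.exp(mbmatc_log)[:, None],
                np.exp(type_log[t])[:, None],
            )
            counts_cols.append(_nb_draw(rng, mu, cfg.nb_dispersion))
            cell_type_l += [t] * n_cells
            tissue_l += [tissue] * n_cells
            cluster_l += [
                MBMATC_CLUSTER if m else t for m in is_mbmatc
            ]

    if cfg.n_qc_fail_cells > 0:
        # deliberately pathological cells: mitochondrial means inflated 50x
        mu = np.exp(type_log[MALIGNANT_TYPE]).copy()
        mu[: cfg.n_mito_genes] *= 50.0
        counts_cols.append(
            _nb_draw(rng, np.repeat(mu[:, None], cfg.n_qc_fail_cells, axis=1), cfg.nb_dispersion)
        )
        cell_type_l += [MALIGNANT_TYPE] * cfg.n_qc_fail_cells
        tissue_l += ["PT"] * cfg.n_qc_fail_cells
        cluster_l += ["qc_fail"] * cfg.n_qc_fail_cells

    counts = np.concatenate(counts_cols, axis=1)
    cell_ids = [f"c{i:06d}" for i in range(counts.shape[1])]
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=cell_ids),
        layer="counts",
        gene_lengths=gene_lengths(cfg),
    )
    labels = pd.DataFrame(
        {
            "cell_type": cell_type_l,
            "tissue": tissue_l,
            "cluster": cluster_l,
            "is_malignant": [t == MALIGNANT_TYPE for t in cell_type_l],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ann = CellAnnotation(labels)
    truth = SyntheticTruth(
        config=cfg,
        planted_signature=GeneSignature("planted_mbmatc", sig_genes, list(effects)),
        signature_effects_log2=effects_ser,
        cluster_profiles=profiles,
        cell_labels=labels,
    )
    return matrix, ann, truth


def simulate_survival(
    f: np.ndarray,
    baseline_hazard: float,
    hazard_beta: float,
    censor_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential event times with hazard ``h0 * exp(beta * f)`` and
    independent exponential censoring; returns columns time, event."""
    f = np.asarray(f, dtype=float)
    rate = baseline_hazard * np.exp(hazard_beta * f)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=f.shape)
    else:
        t_cens = np.full(f.shape, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame({"time": time, "event": event})


def simulate_bulk_cohort(
    cfg: SimulationConfig, truth: SyntheticTruth
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Bulk samples as noisy mixtures of the simulated cluster profiles.

    Sample ``s`` mixes the non-MBMATC cluster profiles with Dirichlet(1)
    weights scaled by ``1 - f_s`` plus ``f_s`` times the MBMATC profile,
    then applies per-gene log-normal noise. Survival couples to ``f_s``
    through the configured hazard model.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_BULK)
    profiles = truth.cluster_profiles
    others = [c for c in profiles.columns if c != MBMATC_CLUSTER]
    a, b = cfg.fraction_beta
    n = cfg.n_bulk_samples
    f = rng.beta(a, b, n)
    w = rng.dirichlet(np.ones(len(others)), size=n)  # n x k
    base = profiles[others].to_numpy() @ w.T  # genes x n
    mix = (1.0 - f)[None, :] * base + f[None, :] * profiles[MBMATC_CLUSTER].to_numpy()[:, None]
    if cfg.bulk_noise_sd > 0:
        mix = mix * np.exp(rng.normal(0.0, cfg.bulk_noise_sd, mix.shape))
    sample_ids = [f"s{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(mix, index=profiles.index, columns=sample_ids),
        layer="counts",
        gene_lengths=gene_lengths(cfg),
    )
    surv = simulate_survival(
        f, cfg.baseline_hazard, cfg.hazard_beta, cfg.censor_rate, rng
    )
    surv.index = pd.Index(sample_ids, name="sample_id")
    out = dataclasses.replace(truth, f_s=pd.Series(f, index=sample_ids))
    return expr, surv, out


def simulate_drug_response(
    cfg: SimulationConfig, truth: SyntheticTruth
) -> tuple[dict[str, DrugSensitivity], SyntheticTruth]:
    """Two database-like sensitivity tables ("ctrp", "gdsc") with shared
    effect structure and independent noise. Lower score = more sensitive."""
    cfg.validate()
    if truth.f_s is None:
        raise ValueError("bulk truth (f_s) required; run simulate_bulk_cohort first")
    rng = cfg.rng(_STREAM_DRUGS)
    drug_ids = [f"d{i:03d}" for i in range(cfg.n_drugs)]
    eff_idx = np.sort(rng.choice(cfg.n_drugs, cfg.n_effective_drugs, replace=False))
    slopes = np.zeros(cfg.n_drugs)
    slopes[eff_idx] = cfg.drug_effect_slope
    # IC50-like baselines on the order of 1; kept below ~0.95 so that a
    # slope-sized group shift is expressible as a log2 fold-change beyond
    # the screen's gate (for a ~ 1.2 the ratio (a - s*fh)/(a - s*fl) cannot
    # reach 2^-0.1 even noise-free)
    baselines = rng.uniform(0.65, 0.95, cfg.n_drugs)
    f = truth.f_s.to_numpy()
    tables: dict[str, DrugSensitivity] = {}
    for db in ("ctrp", "gdsc"):
        scores = (
            baselines[None, :]
            - f[:, None] * slopes[None, :]
            + rng.normal(0.0, cfg.drug_noise_sd, (len(f), cfg.n_drugs))
        )
        tables[db] = DrugSensitivity(
            database=db,
            scores=pd.DataFrame(scores, index=truth.f_s.index, columns=drug_ids),
            provenance="simulated",
        )
    out = dataclasses.replace(truth, effective_drug_ids=[drug_ids[i] for i in eff_idx])
    return tables, out
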