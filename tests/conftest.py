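import numpy as np
import pandas as pd
import pytest

import mbmindex as mx

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """One full synthetic study at default conditions, shared read-only:
    cells -> lognorm -> derived signature -> OCLR model -> scored cohort."""
    cfg = mx.SimulationConfig(seed=STUDY_SEED)
    cells, ann, truth = mx.simulate_cells(cfg)
    lognorm = mx.log_normalize(cells)
    signature = mx.derive_signature(lognorm, ann, "MBMATC")
    bulk, surv, truth = mx.simulate_bulk_cohort(cfg, truth)
    tpm = mx.tpm_normalize(bulk)
    tab = ann.table
    malignant = tab.index[tab["is_malignant"]]
    target = [c for c in malignant if tab.loc[c, "cluster"] == "MBMATC"]
    train = lognorm.subset_genes(signature.genes).subset_obs(target)
    ref_mean = lognorm.subset_genes(signature.genes).values.loc[:, malignant].mean(axis=1)
    model = mx.fit_oclr(train, center_by=ref_mean)
    results = mx.stratify(mx.scale_index(mx.score_samples(model, tpm)))
    return {
        "cfg": cfg,
        "cells": cells,
        "ann": ann,
        "truth": truth,
        "lognorm": lognorm,
        "signature": signature,
        "bulk": bulk,
        "surv": surv,
        "tpm": tpm,
        "model": model,
        "results": results,
    }


@pytest.fixture
def tiny_counts():
    """4 genes x 3 cells counts matrix with one mito gene and lengths."""
    genes = ["MT-1", "gA", "gB", "gC"]
    values = pd.DataFrame(
        [[1, 30, 0], [5, 10, 2], [3, 0, 4], [1, 10, 6]],
        index=genes,
        columns=["c1", "c2", "c3"],
        dtype=float,
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0, 1000.0], index=genes)
    return mx.ExpressionMatrix(values, layer="counts", gene_lengths=lengths)


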