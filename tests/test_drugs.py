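"""Sensitivity imputation, Mann-Whitney U, and the two-tiered screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import mbmindex as mx
from mbmindex.drugs import DrugSensitivity


def _em(values, genes, obs, layer="lognorm"):
    return mx.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=obs, dtype=float), layer=layer
    )


class TestMannWhitney:
    def test_textbook_enumeration_example(self):
        u, p = mx.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        _, p = mx.mann_whitney_u([1, 2, 3], [1, 2, 3], mode="exact")
        assert p == pytest.approx(1.0)

    def test_all_tied_p_one(self):
        _, p = mx.mann_whitney_u([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_exact_matches_full_enumeration_all_small_splits(self):
        # every two-group split of 8 distinct values: compare with an
        # independent enumeration written from the definition
        values = np.array([3.1, -0.2, 5.7, 1.1, 0.0, 2.2, 9.4, -3.3])
        for na in range(2, 7):
            pooled = values
            for comb in itertools.combinations(range(8), na):
                sel = np.zeros(8, dtype=bool)
                sel[list(comb)] = True
                a, b = pooled[sel], pooled[~sel]
                u_obs, p_obs = mx.mann_whitney_u(a, b, mode="exact")
                # oracle
                mu = na * (8 - na) / 2
                devs = []
                for c2 in itertools.combinations(range(8), na):
                    s2 = np.zeros(8, dtype=bool)
                    s2[list(c2)] = True
                    u = (pooled[s2][:, None] > pooled[~s2][None, :]).sum()
                    devs.append(abs(u - mu))
                dev_obs = abs(u_obs - mu)
                expect = np.mean([d >= dev_obs - 1e-12 for d in devs])
                assert p_obs == pytest.approx(expect, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_exact_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        a, b = rng.normal(size=na), rng.normal(size=nb)
        _, p = mx.mann_whitney_u(a, b, mode="exact")
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_normal_approx_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=25)
            b = rng.normal(0.4, 1, size=30)
            _, p = mx.mann_whitney_u(a, b, mode="normal_approx")
            ref = scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_large_sample_calibration(self):
        rng = np.random.default_rng(2)
        n_reps, rej = 400, 0
        for _ in range(n_reps):
            a, b = rng.normal(size=30), rng.normal(size=30)
            _, p = mx.mann_whitney_u(a, b)
            rej += p < 0.05
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rej / n_reps - 0.05) < ci + 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mx.mann_whitney_u([], [1.0])


class TestImputation:
    def _reference(self, rng, p=40, n=50):
        genes = [f"g{i}" for i in range(p)]
        lines = [f"L{i}" for i in range(n)]
        R = rng.normal(0, 1, (p, n))
        return _em(R, genes, lines), R

    def test_interpolation_limit(self):
        # target identical to a reference line, tiny ridge, p < n
        rng = np.random.default_rng(3)
        ref, R = self._reference(rng, p=10, n=40)
        resp = pd.DataFrame({"d": R.T @ rng.normal(0, 1, 10)}, index=ref.obs_ids)
        tgt = _em(R[:, [5]], list(ref.gene_ids), ["t0"])
        sens = mx.impute_sensitivity(ref, resp, tgt, ridge_lambda=1e-8)
        # prediction equals that line's fitted value; with p<n and no noise
        # the fit is essentially exact
        assert sens.scores.loc["t0", "d"] == pytest.approx(resp.loc["L5", "d"], rel=1e-3)

    def test_null_response_shrinks_to_mean(self):
        rng = np.random.default_rng(4)
        ref, R = self._reference(rng)
        y = rng.normal(5, 1, 50)  # independent of expression
        resp = pd.DataFrame({"d": y}, index=ref.obs_ids)
        tgt = _em(rng.normal(0, 1, (40, 30)), list(ref.gene_ids),
                  [f"t{i}" for i in range(30)])
        sens = mx.impute_sensitivity(ref, resp, tgt)
        assert abs(sens.scores["d"].mean() - y.mean()) < 0.5
        assert sens.scores["d"].std() < y.std()

    def test_linear_truth_out_of_sample(self):
        rng = np.random.default_rng(5)
        p = 30
        beta = rng.normal(0, 1, p)
        ref, R = self._reference(rng, p=p, n=80)
        resp = pd.DataFrame(
            {"d": R.T @ beta + rng.normal(0, 1.0, 80)}, index=ref.obs_ids
        )
        T = rng.normal(0, 1, (p, 50))
        tgt = _em(T, list(ref.gene_ids), [f"t{i}" for i in range(50)])
        sens = mx.impute_sensitivity(ref, resp, tgt)
        r = np.corrcoef(sens.scores["d"], T.T @ beta)[0, 1]
        assert r >= 0.8

    def test_constant_response_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        ref, R = self._reference(rng, p=15, n=10)
        resp = pd.DataFrame(
            {"flat": np.ones(10), "ok": R.T @ rng.normal(0, 1, 15)},
            index=ref.obs_ids,
        )
        tgt = _em(rng.normal(0, 1, (15, 5)), list(ref.gene_ids),
                  [f"t{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="constant"):
            sens = mx.impute_sensitivity(ref, resp, tgt)
        assert list(sens.scores.columns) == ["ok"]

    def test_no_shared_genes_errors(self):
        rng = np.random.default_rng(7)
        ref, _ = self._reference(rng, p=12, n=5)
        tgt = _em(rng.normal(0, 1, (3, 2)), ["x1", "x2", "x3"], ["t0", "t1"])
        resp = pd.DataFrame({"d": rng.normal(size=5)}, index=ref.obs_ids)
        with pytest.raises(ValueError, match="shared genes"):
            mx.impute_sensitivity(ref, resp, tgt)


def _screen_tables(rng, n_samples=60, n_drugs=8, effect=0.0):
    samples = [f"s{i}" for i in range(n_samples)]
    drugs = [f"d{i}" for i in range(n_drugs)]
    hi = np.arange(n_samples) < n_samples // 2
    out = {}
    for db in ("A", "B"):
        scores = rng.normal(1.0, 0.1, (n_samples, n_drugs))
        scores[hi, 0] -= effect  # drug 0 optionally sensitizing in hi group
        out[db] = DrugSensitivity(db, pd.DataFrame(scores, index=samples, columns=drugs))
    labels = pd.Series(hi, index=samples)
    return out, labels


class TestScreen:
    def test_fold_change_gate_arithmetic(self):
        # target mean 0.9 vs comparator 1.0: log2FC ~ -0.152 passes the gate
        assert np.log2(0.9 / 1.0) < -0.1

    def test_identical_distributions_fail(self):
        rng = np.random.default_rng(8)
        tables, labels = _screen_tables(rng, effect=0.0)
        screen = mx.two_tier_screen(tables, {"arm": labels})
        assert screen.candidates["arm"] == []

    def test_strong_effect_detected_and_intersected(self):
        rng = np.random.default_rng(9)
        tables, labels = _screen_tables(rng, effect=0.15)
        screen = mx.two_tier_screen(tables, {"arm": labels})
        assert screen.candidates["arm"] == ["d0"]
        t = screen.table
        assert t.loc[(t.drug == "d0") & (t.arm == "arm"), "passed"].all()
        # intersection column consistent with the pass columns
        assert set(t.loc[t.intersection, "drug"]) == {"d0"}

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(10)
        tables, labels = _screen_tables(rng, effect=0.15)
        scaled = {
            db: DrugSensitivity(db, s.scores * 7.3) for db, s in tables.items()
        }
        s1 = mx.two_tier_screen(tables, {"arm": labels})
        s2 = mx.two_tier_screen(scaled, {"arm": labels})
        pd.testing.assert_series_equal(s1.table["passed"], s2.table["passed"])
        assert np.allclose(s1.table["log2fc"], s2.table["log2fc"])

    def test_candidates_monotone_in_thresholds(self):
        rng = np.random.default_rng(11)
        tables, labels = _screen_tables(rng, effect=0.12)
        loose = mx.two_tier_screen(tables, {"arm": labels}, fc_threshold=-0.05)
        tight = mx.two_tier_screen(tables, {"arm": labels}, fc_threshold=-0.15)
        assert set(tight.candidates["arm"]) <= set(loose.candidates["arm"])

    def test_nonpositive_mean_errors_with_drug_name(self):
        rng = np.random.default_rng(12)
        tables, labels = _screen_tables(rng)
        tables["A"].scores["d3"] = -1.0
        with pytest.raises(ValueError, match="d3"):
            mx.two_tier_screen(tables, {"arm": labels})


class TestIndexSensitivityCorrelation:
    def _index(self, values):
        return pd.DataFrame(
            {"index": values}, index=[f"s{i}" for i in range(len(values))]
        )

    def test_monotone_construction_rho_minus_one(self):
        idx = self._index(np.linspace(0, 1, 12))
        scores = pd.DataFrame(
            {"d": 1.0 - 0.3 * np.linspace(0, 1, 12)}, index=idx.index
        )
        sens = DrugSensitivity("db", scores)
        rho, p = mx.index_sensitivity_correlation(sens, idx, "d")
        assert rho == pytest.approx(-1.0)
        assert p < 1e-6

    def test_small_n_matches_bruteforce_permutation(self):
        rng = np.random.default_rng(13)
        idx = self._index(rng.uniform(0, 1, 6))
        scores = pd.DataFrame({"d": rng.normal(1, 0.2, 6)}, index=idx.index)
        sens = DrugSensitivity("db", scores)
        rho, p = mx.index_sensitivity_correlation(sens, idx, "d")
        # oracle: rank-then-Pearson plus exhaustive permutation p
        rx = scipy.stats.rankdata(scores["d"])
        ry = scipy.stats.rankdata(idx["index"])
        rho_ref = float(np.corrcoef(rx, ry)[0, 1])
        count = total = 0
        for perm in itertools.permutations(range(6)):
            r = float(np.corrcoef(rx[list(perm)], ry)[0, 1])
            total += 1
            count += abs(r) >= abs(rho_ref) - 1e-12
        assert rho == pytest.approx(rho_ref, abs=1e-12)
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_null_drug_ci_covers_zero(self, study):
        cfg = study["cfg"]
        truth = study["truth"]
        tables, truth = mx.simulate_drug_response(cfg, truth)
        null_drug = next(
            d for d in tables["ctrp"].scores.columns
            if d not in truth.effective_drug_ids
        )
        rho, p = mx.index_sensitivity_correlation(
            tables["ctrp"], study["results"], null_drug
        )
        n = len(study["results"])
        assert abs(np.arctanh(rho)) < 2.5 / np.sqrt(n - 3)

    def test_constant_vector_flagged(self):
        idx = self._index(np.linspace(0, 1, 6))
        sens = DrugSensitivity("db", pd.DataFrame({"d": np.ones(6)}, index=idx.index))
        with pytest.raises(ValueError, match="constant"):
            mx.index_sensitivity_correlation(sens, idx, "d")
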