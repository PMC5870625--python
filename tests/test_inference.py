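"""Activity-score statistics against independent oracles and invariants."""

import math
from itertools import combinations

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hs

from kinfer.inference import (
    ActivityScoreTable,
    ConditionVector,
    DegenerateBackgroundError,
    infer_all,
    ksea,
    ks_test,
    mlr_fit,
    wilcoxon_test,
    ztest,
)
from kinfer.io import SiteQuantMatrix
from kinfer.network import KinaseSubstrateNetwork, KSInteraction

from conftest import make_cv, regulon_of


def brute_force_es(fc, mask, weight_exponent=1.0):
    """Explicit running-sum enrichment score (independent of the package's
    vectorized position-based computation)."""
    order = np.argsort(-fc, kind="stable")
    fcr, mr = fc[order], mask[order]
    n_r = np.sum(np.abs(fcr[mr]) ** weight_exponent)
    n, k = fc.size, int(mr.sum())
    run, best = 0.0, 0.0
    for i in range(n):
        if mr[i]:
            run += np.abs(fcr[i]) ** weight_exponent / n_r
        else:
            run -= 1.0 / (n - k)
        if abs(run) > abs(best):
            best = run
    return best


class TestZtest:
    def test_zero_shift_gives_zero_score(self):
        # substrates' mean equals the background mean exactly
        cv = make_cv([1.0, -1.0, 2.0, -2.0, 0.0])
        score = ztest(cv, regulon_of([2, 4, 3]))  # mean 0 = background mean
        assert score.statistic == pytest.approx(0.0)
        assert score.p_value == pytest.approx(1.0)
        assert score.signed_score == pytest.approx(0.0)

    def test_matches_textbook_formula(self, rng):
        fc = rng.normal(size=200)
        fc[:5] += 2.0
        cv = make_cv(fc)
        score = ztest(cv, regulon_of(range(5)))
        z_ref = (fc[:5].mean() - fc.mean()) * math.sqrt(5) / fc.std(ddof=1)
        assert score.statistic == pytest.approx(z_ref, abs=1e-10)
        assert score.p_value == pytest.approx(2 * st.norm.sf(abs(z_ref)), abs=1e-10)

    def test_antisymmetric_under_negation(self, rng):
        fc = rng.normal(size=60)
        reg = regulon_of(range(8))
        a = ztest(make_cv(fc), reg)
        b = ztest(make_cv(-fc), reg)
        assert b.statistic == pytest.approx(-a.statistic)
        assert b.p_value == pytest.approx(a.p_value)
        assert b.signed_score == pytest.approx(-a.signed_score)

    def test_degenerate_background_raises(self):
        with pytest.raises(DegenerateBackgroundError):
            ztest(make_cv([1.0, 1.0, 1.0]), regulon_of([0]))


class TestKSTest:
    def test_identical_distributions_give_d_zero(self):
        cv = make_cv([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        score = ks_test(cv, regulon_of([0, 1, 2]))
        assert score.statistic == pytest.approx(0.0)
        assert score.p_value == pytest.approx(1.0)

    def test_separated_distributions_give_d_one(self):
        cv = make_cv([5.0, 6.0, 7.0, -1.0, -2.0, -3.0])
        score = ks_test(cv, regulon_of([0, 1, 2]))
        assert score.statistic == pytest.approx(1.0)

    def test_d_matches_double_loop_ecdf_oracle(self, rng):
        fc = np.round(rng.normal(size=40), 1)  # ties on purpose
        reg_idx = rng.choice(40, 7, replace=False)
        cv = make_cv(fc)
        score = ks_test(cv, regulon_of(reg_idx))
        sub = fc[reg_idx]
        bg = np.delete(fc, reg_idx)
        d_ref = max(
            abs(np.mean(sub <= t) - np.mean(bg <= t)) for t in fc
        )
        assert score.statistic == pytest.approx(d_ref, abs=1e-12)

    def test_matches_scipy_asymptotic(self, rng):
        for _ in range(20):
            fc = rng.normal(size=int(rng.integers(30, 120)))
            k = int(rng.integers(3, 12))
            idx = rng.choice(fc.size, k, replace=False)
            score = ks_test(make_cv(fc), regulon_of(idx))
            ref = st.ks_2samp(fc[idx], np.delete(fc, idx), method="asymp")
            assert score.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert score.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestWilcoxon:
    def test_top_ranked_substrates_minimize_p(self, rng):
        fc = np.sort(rng.normal(size=12))[::-1]
        cv = make_cv(fc)
        top = wilcoxon_test(cv, regulon_of(range(4))).p_value
        for _ in range(50):
            idx = rng.choice(12, 4, replace=False)
            assert wilcoxon_test(cv, regulon_of(idx)).p_value >= top - 1e-12

    def test_all_identical_values_give_p_one(self):
        cv = make_cv([2.0] * 10)
        assert wilcoxon_test(cv, regulon_of([0, 1])).p_value == pytest.approx(1.0)

    def test_label_swap_preserves_p(self, rng):
        fc = rng.normal(size=20)
        a = wilcoxon_test(make_cv(fc), regulon_of(range(6)))
        b = wilcoxon_test(make_cv(fc), regulon_of(range(6, 20)))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            fc = np.round(rng.normal(size=int(rng.integers(20, 80))), 1)
            k = int(rng.integers(3, 10))
            idx = rng.choice(fc.size, k, replace=False)
            score = wilcoxon_test(make_cv(fc), regulon_of(idx))
            ref = st.mannwhitneyu(
                fc[idx], np.delete(fc, idx), alternative="two-sided",
                method="asymptotic",
            )
            assert score.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestKSEA:
    def test_top_block_substrates_reach_es_one(self):
        fc = np.array([5.0, 4.0, 3.0, 0.5, -0.5, -1.0, -2.0, 0.1])
        score = ksea(make_cv(fc), regulon_of([0, 1, 2]), n_perm=100, seed=0)
        assert score.statistic == pytest.approx(1.0)

    def test_es_matches_brute_force_running_sum(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            k = int(rng.integers(1, n - 1))
            fc = rng.normal(size=n)
            idx = rng.choice(n, k, replace=False)
            mask = np.isin(np.arange(n), idx)
            score = ksea(make_cv(fc), regulon_of(idx), n_perm=10, seed=0)
            assert score.statistic == pytest.approx(
                brute_force_es(fc, mask), abs=1e-12
            )

    def test_exhaustive_p_equals_subset_enumeration(self, rng):
        n, k = 8, 3
        fc = rng.normal(size=n)
        idx = [0, 4, 6]
        score = ksea(make_cv(fc), regulon_of(idx), null="exhaustive")
        obs = brute_force_es(fc, np.isin(np.arange(n), idx))
        null = [
            brute_force_es(fc, np.isin(np.arange(n), c))
            for c in combinations(range(n), k)
        ]
        p_ref = np.mean([abs(e) >= abs(obs) for e in null])
        assert score.p_value == pytest.approx(p_ref, abs=1e-15)

    def test_montecarlo_p_within_binomial_error_of_exhaustive(self, rng):
        n, k, n_perm = 6, 2, 10_000
        fc = rng.normal(size=n)
        idx = [1, 3]
        exact = ksea(make_cv(fc), regulon_of(idx), null="exhaustive").p_value
        mc = ksea(make_cv(fc), regulon_of(idx), n_perm=n_perm, seed=3).p_value
        tol = 3 * math.sqrt(exact * (1 - exact) / n_perm) + 2 / n_perm
        assert abs(mc - exact) <= tol

    def test_same_seed_reproduces_p(self, rng):
        fc = rng.normal(size=50)
        reg = regulon_of(range(5))
        a = ksea(make_cv(fc), reg, n_perm=500, seed=9)
        b = ksea(make_cv(fc), reg, n_perm=500, seed=9)
        assert a.p_value == b.p_value

    def test_all_zero_substrate_fold_changes_degenerate(self):
        fc = np.array([0.0, 0.0, 1.0, 2.0, -1.0])
        with pytest.raises(DegenerateBackgroundError):
            ksea(make_cv(fc), regulon_of([0, 1]), n_perm=10, seed=0)


class TestMLR:
    def test_identity_connectivity_recovers_y_at_lambda_zero(self):
        fc = np.array([1.0, -2.0, 3.0])
        ints = [
            KSInteraction(f"K{i}", f"P{i:04d}", 8, "S") for i in range(3)
        ]
        scores, fit = mlr_fit(make_cv(fc), KinaseSubstrateNetwork(ints), ridge_lambda=0.0)
        np.testing.assert_allclose(sorted(fit.beta), sorted(fc), atol=1e-10)

    @given(hs.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_normal_equations_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 50))
        nk = int(rng.integers(2, 6))
        fc = rng.normal(size=n)
        ints = []
        for j in range(nk):
            for i in rng.choice(n, int(rng.integers(2, 8)), replace=False):
                ints.append(KSInteraction(f"K{j}", f"P{i:04d}", 8, "S"))
        lam = float(rng.uniform(0.01, 1.0))
        _, fit = mlr_fit(make_cv(fc), KinaseSubstrateNetwork(ints), ridge_lambda=lam)
        ref = np.linalg.solve(
            fit.X.T @ fit.X + lam * np.eye(fit.X.shape[1]), fit.X.T @ fit.Y
        )
        np.testing.assert_allclose(fit.beta, ref, atol=1e-8)

    def test_identical_regulons_share_beta(self, rng):
        fc = rng.normal(size=30)
        ints = []
        for kinase in ("K1", "K2"):
            for i in range(5):
                ints.append(KSInteraction(kinase, f"P{i:04d}", 8, "S"))
        scores, _ = mlr_fit(make_cv(fc), KinaseSubstrateNetwork(ints), ridge_lambda=0.1)
        assert scores[0].signed_score == pytest.approx(scores[1].signed_score, abs=1e-10)

    def test_antisymmetric_under_negation(self, rng, toy_network):
        fc = rng.normal(size=20)
        _, a = mlr_fit(make_cv(fc), toy_network)
        _, b = mlr_fit(make_cv(-fc), toy_network)
        np.testing.assert_allclose(a.beta, -b.beta, atol=1e-10)


class TestInferAll:
    def make_matrix(self, rng, n_sites=30, conditions=("c1", "c2", "c3")):
        import pandas as pd

        idx = pd.MultiIndex.from_tuples(
            [(f"P{i:04d}", 8, "S") for i in range(n_sites)],
            names=["protein", "position", "residue"],
        )
        return SiteQuantMatrix(
            data=pd.DataFrame(
                rng.normal(size=(n_sites, len(conditions))), index=idx,
                columns=list(conditions),
            ),
            normalized=True,
        )

    def test_scores_every_pair(self, rng, toy_network):
        m = self.make_matrix(rng)
        table = infer_all(m, toy_network, method="ztest")
        assert len(table) == 6  # 2 kinases x 3 conditions

    def test_unquantified_cell_absent(self, rng, toy_network):
        m = self.make_matrix(rng)
        m.data.loc[[("P0000", 8, "S"), ("P0001", 8, "S"), ("P0002", 8, "S")], "c1"] = np.nan
        table = infer_all(m, toy_network, method="ztest")
        assert table.get("A", "c1") is None
        assert table.get("A", "c2") is not None
        assert len(table) == 5

    def test_invariant_to_site_row_order(self, rng, toy_network):
        m = self.make_matrix(rng)
        perm = rng.permutation(len(m.data))
        m_perm = SiteQuantMatrix(data=m.data.iloc[perm], normalized=True)
        for method in ("ztest", "ks", "mlr"):
            a = infer_all(m, toy_network, method=method).to_frame()
            b = infer_all(m_perm, toy_network, method=method).to_frame()
            a = a.sort_values(["kinase", "condition"]).reset_index(drop=True)
            b = b.sort_values(["kinase", "condition"]).reset_index(drop=True)
            assert np.allclose(a.signed_score, b.signed_score, atol=1e-10)

    def test_unknown_method_rejected(self, rng, toy_network):
        with pytest.raises(ValueError, match="unknown method"):
            infer_all(self.make_matrix(rng), toy_network, method="tremble")

    def test_gsea_deterministic_given_seed(self, rng, toy_network):
        m = self.make_matrix(rng)
        a = infer_all(m, toy_network, method="gsea", n_perm=200, seed=4).to_frame()
        b = infer_all(m, toy_network, method="gsea", n_perm=200, seed=4).to_frame()
        assert (a.p_value == b.p_value).all()

    def test_activity_matrix_shape(self, rng, toy_network):
        table = infer_all(self.make_matrix(rng), toy_network, method="ztest")
        pivot = table.activity_matrix()
        assert pivot.shape == (2, 3)
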