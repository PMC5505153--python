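import numpy as np
import pytest
from scipy.stats import chi2

from inote.core_data import Cohort, DiseaseModel
from inote.gene_kernels import build_kernel
from inote.null_dist import (
    PerturbationEngine,
    davies_p,
    empirical_p,
    mixture_weights,
    mixture_weights_from_design,
    perturb_q,
    proportion_p,
    ranked_p,
    satterthwaite_p,
)
from inote.null_model import fit_null

from conftest import make_block, make_cohort


def _mc_mixture_tail(lam, q, n_draws=1_000_000, seed=123):
    """Monte-Carlo oracle for P(sum lam_k chi2_1 > q)."""
    rng = np.random.default_rng(seed)
    total = np.zeros(n_draws)
    for lk in lam:
        total += lk * rng.standard_normal(n_draws) ** 2
    p = (total > q).mean()
    se = np.sqrt(p * (1 - p) / n_draws)
    return p, se


class TestSatterthwaite:
    def test_single_weight_is_exact_chi2_1(self):
        q = 2.7
        assert satterthwaite_p(q, np.array([1.0])) == pytest.approx(
            chi2.sf(q, 1), rel=1e-12)

    def test_equal_weights_are_exact_chi2_k(self):
        q = 5.3
        assert satterthwaite_p(q, np.ones(3)) == pytest.approx(
            chi2.sf(q, 3), rel=1e-12)

    def test_unequal_weights_close_to_monte_carlo(self):
        lam = np.array([4.0, 1.0, 0.25])
        p_mc, _ = _mc_mixture_tail(lam, 8.0)
        assert satterthwaite_p(8.0, lam) == pytest.approx(p_mc, abs=0.02)

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            satterthwaite_p(1.0, np.zeros(3))


class TestDavies:
    def test_chi2_1_critical_value(self):
        assert davies_p(3.841458820694124, np.array([1.0])) == pytest.approx(
            0.05, abs=5e-5)

    @pytest.mark.parametrize("lam,q", [
        ((2.0, 0.5), 3.0),
        ((2.0, 0.5), 7.5),
        ((5.0, 1.0, 1.0, 0.2), 12.0),
        ((0.03, 0.02, 0.01), 0.1),
    ])
    def test_agrees_with_monte_carlo(self, lam, q):
        p_mc, se = _mc_mixture_tail(np.array(lam), q)
        assert davies_p(q, np.array(lam)) == pytest.approx(p_mc, abs=3 * se + 1e-6)

    def test_zero_statistic_gives_p_one(self):
        assert davies_p(0.0, np.array([1.0, 2.0])) == 1.0

    def test_matches_exact_chi2_tail_across_range(self):
        # inversion accuracy is absolute (acc=1e-6), so far tails are
        # compared on the absolute scale
        for q in (0.01, 1.0, 10.0, 30.0):
            assert davies_p(q, np.array([1.0])) == pytest.approx(
                max(chi2.sf(q, 1), 1e-12), rel=1e-3, abs=1e-6)


class TestMixtureWeights:
    def test_rank_one_reduction_matches_chi2_scaling(self):
        """Intercept-only null + single G column: p is a scaled chi2_1 tail."""
        cohort = make_cohort(n=80, r=1, seed=5)
        null = fit_null(cohort)
        block = make_block(n=80, p=2, seed=5)
        kt = build_kernel(block, null, DiseaseModel.G)
        assert len(kt.eigvals) == 1
        lam = kt.eigvals[0]
        assert davies_p(kt.q_obs, kt.eigvals) == pytest.approx(
            chi2.sf(kt.q_obs / lam, 1), rel=1e-4)

    def test_matches_brute_force_score_covariance_construction(self):
        """lambda == eigenvalues of A D A' built element-by-element."""
        cohort = make_cohort(n=20, r=2, seed=8)
        null = fit_null(cohort)
        block = make_block(n=20, p=2, seed=8)
        kt = build_kernel(block, null, DiseaseModel.M)

        v = kt.v_matrix
        u = np.hstack([null.x, v])  # U_i = (X_i', V_i')
        d = u.T @ (u * null.w_diag[:, None]) / null.n
        r = null.x.shape[1]
        d_xx, d_xv = d[:r, :r], d[:r, r:]
        a = np.hstack([-d_xv.T @ np.linalg.inv(d_xx), np.eye(v.shape[1])])
        lam_dense = np.linalg.eigvalsh(a @ d @ a.T)
        lam_dense = np.sort(lam_dense[lam_dense > 1e-12])[::-1]
        assert np.allclose(kt.eigvals, lam_dense, rtol=1e-8)

    def test_duplicated_column_doubles_the_weight(self, null60):
        m = make_block(n=60, p=1, seed=3).m
        lam1 = mixture_weights_from_design(m, null60)
        lam2 = mixture_weights_from_design(np.hstack([m, m]), null60)
        assert len(lam1) == len(lam2) == 1
        assert lam2[0] == pytest.approx(2 * lam1[0], rel=1e-10)


class TestPerturbation:
    def test_sample_mean_matches_moment_identity(self):
        """mean of {Q_hat} -> sum of mixture weights, within 3 SE at B=5000.

        Balanced intercept-only design, where the empirical score
        covariance equals the plug-in one exactly and the identity is pure
        Monte-Carlo error.
        """
        cohort = make_cohort(n=60, r=1, seed=3)
        null = fit_null(cohort)
        block = make_block(n=60, p=4, seed=11)
        kt = build_kernel(block, null, DiseaseModel.MGC)
        engine = PerturbationEngine.create(60, b=5000, seed=42)
        q_null = perturb_q(kt, engine, null)
        se = q_null.std(ddof=1) / np.sqrt(len(q_null))
        assert q_null.mean() == pytest.approx(kt.eigvals.sum(), abs=3 * se)

    def test_cross_engine_quantile_agreement(self, null60):
        """Perturbation 95th percentile vs the Davies 5% critical value."""
        from scipy.optimize import brentq

        block = make_block(n=60, p=3, seed=12)
        kt = build_kernel(block, null60, DiseaseModel.MG)
        engine = PerturbationEngine.create(60, b=10000, seed=7)
        q_null = perturb_q(kt, engine, null60)
        q_emp = np.quantile(q_null, 0.95)
        q_davies = brentq(lambda q: davies_p(q, kt.eigvals) - 0.05,
                          1e-6, 100 * kt.eigvals.sum())
        assert abs(q_emp - q_davies) / q_davies < 0.05

    def test_fixed_seed_is_bit_identical(self, null60):
        block = make_block(n=60, p=2, seed=13)
        kt = build_kernel(block, null60, DiseaseModel.M)
        q1 = perturb_q(kt, PerturbationEngine.create(60, b=200, seed=9), null60)
        q2 = perturb_q(kt, PerturbationEngine.create(60, b=200, seed=9), null60)
        assert np.array_equal(q1, q2)

    def test_small_b_warns(self, caplog):
        with caplog.at_level("WARNING"):
            PerturbationEngine.create(10, b=50, seed=0)
        assert any("resolution" in r.message for r in caplog.records)

    def test_engine_size_mismatch_errors(self, null60):
        engine = PerturbationEngine.create(10, b=200, seed=0)
        with pytest.raises(ValueError, match="n="):
            engine.scores(null60)


class TestEmpiricalP:
    def test_add_one_rule(self):
        draws = np.arange(999, dtype=float)
        assert empirical_p(-1.0, draws) == 1.0
        assert empirical_p(2000.0, draws) == pytest.approx(0.001)
        assert empirical_p(499.5, draws) == pytest.approx(0.5, abs=0.01)

    def test_proportion_p_can_reach_zero(self):
        draws = np.arange(100, dtype=float)
        assert proportion_p(1e9, draws) == 0.0
        assert proportion_p(-1.0, draws) == 1.0

    def test_ranked_p_is_uniform_on_grid(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(500)
        p = ranked_p(draws)
        assert set(np.round(p * 500).astype(int)) == set(range(1, 501))
        # top draw gets the floor 1/B; bottom draw gets 1
        assert p[np.argmax(draws)] == pytest.approx(1 / 500)
        assert p[np.argmin(draws)] == 1.0
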