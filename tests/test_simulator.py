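import numpy as np
import pytest
from scipy.special import logit

from inote.core_data import DiseaseModel
from inote.simulator import (
    SimScenario,
    simulate_dataset,
    simulate_expression,
    simulate_methylation,
    simulate_outcome,
    run_size_power_study,
    _assign_causal,
)


def _latent(meth_block):
    return logit(meth_block)  # inverse of the logistic map, exact


class TestMethylation:
    def test_independent_loci_when_rho_zero(self):
        scn = SimScenario(j_genes=2, rho_within=0.0, rho_between_meth=0.0)
        meth = simulate_methylation(scn, np.random.default_rng(1))
        corr = np.corrcoef(_latent(meth[0]).T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_within_gene_latent_correlation(self):
        scn = SimScenario(j_genes=3)
        meth = simulate_methylation(scn, np.random.default_rng(1))
        offs = []
        for m in meth:
            corr = np.corrcoef(_latent(m).T)
            offs.append(corr[~np.eye(corr.shape[0], dtype=bool)].mean())
        assert np.mean(offs) == pytest.approx(0.8, abs=0.05)

    def test_between_gene_latent_correlation(self):
        scn = SimScenario(j_genes=10)
        meth = simulate_methylation(scn, np.random.default_rng(2))
        causal = np.column_stack([_latent(m[:, 0]) for m in meth])
        corr = np.corrcoef(causal.T)
        off = corr[~np.eye(10, dtype=bool)].mean()
        assert off == pytest.approx(0.3, abs=0.06)

    def test_values_in_unit_interval_and_deterministic(self):
        scn = SimScenario(j_genes=2)
        m1 = simulate_methylation(scn, np.random.default_rng(5))
        m2 = simulate_methylation(scn, np.random.default_rng(5))
        assert all((b > 0).all() and (b < 1).all() for b in m1)
        assert all(np.array_equal(a, b) for a, b in zip(m1, m2))


class TestExpression:
    def test_between_gene_covariance_without_signal(self):
        """delta=0: expression correlation across genes ~ 0.7."""
        scn = SimScenario(j_genes=10, delta=0.0)
        rng = np.random.default_rng(3)
        meth = simulate_methylation(scn, rng)
        expr = simulate_expression(meth, scn, rng)
        corr = np.corrcoef(expr.T)
        off = corr[~np.eye(10, dtype=bool)].mean()
        assert off == pytest.approx(0.7, abs=0.05)

    def test_strong_delta_couples_expression_to_causal_cpg(self):
        """corr(G_j, M_causal_j) = delta*sd(M)/sqrt(delta^2 var(M)+1) -> 1."""
        scn = SimScenario(j_genes=4, rho_within=0.0, rho_between_meth=0.0,
                          rho_between_expr=0.0, delta=20.0)
        rng = np.random.default_rng(4)
        meth = simulate_methylation(scn, rng)
        expr = simulate_expression(meth, scn, rng)
        corrs = [np.corrcoef(meth[j][:, 0], expr[:, j])[0, 1] for j in range(4)]
        sd_m = np.std(meth[0][:, 0])
        analytic = 20 * sd_m / np.sqrt(400 * sd_m**2 + 1)
        assert min(corrs) > 0.9
        assert np.mean(corrs) == pytest.approx(analytic, abs=0.03)


class TestOutcome:
    def test_null_prevalence_matches_target(self):
        scn = SimScenario(j_genes=3, kappa=0.0, base_prevalence=0.3)
        rng = np.random.default_rng(6)
        meth = simulate_methylation(scn, rng)
        expr = simulate_expression(meth, scn, rng)
        y, sample, assignment = simulate_outcome(meth, expr, scn, rng)
        assert assignment == {}
        assert y.mean() == pytest.approx(0.3, abs=0.05)
        assert sample.size == 200

    def test_prevalence_held_under_strong_effects(self):
        scn = SimScenario(j_genes=10, kappa=3.0, model_mix=3,
                          signal_density=0.5, base_prevalence=0.3)
        rng = np.random.default_rng(7)
        meth = simulate_methylation(scn, rng)
        expr = simulate_expression(meth, scn, rng)
        y, _, _ = simulate_outcome(meth, expr, scn, rng)
        assert y.mean() == pytest.approx(0.3, abs=0.06)

    def test_one_third_mixture_splits_ten_causal_genes_4_3_3(self):
        scn = SimScenario(j_genes=50, signal_density=0.2, model_mix=7, kappa=1.0)
        assignment = _assign_causal(scn, np.random.default_rng(8))
        assert len(assignment) == 10
        counts = {m: 0 for m in (DiseaseModel.M, DiseaseModel.MG, DiseaseModel.MGC)}
        for m in assignment.values():
            counts[m] += 1
        assert [counts[DiseaseModel.M], counts[DiseaseModel.MG],
                counts[DiseaseModel.MGC]] == [4, 3, 3]

    def test_insufficient_cases_is_explicit_error(self):
        scn = SimScenario(j_genes=2, base_prevalence=0.05)
        with pytest.raises(RuntimeError, match="cases"):
            simulate_dataset(scn, seed=9)


class TestDataset:
    def test_case_control_composition_and_determinism(self):
        scn = SimScenario(j_genes=4, kappa=0.0)
        cohort, blocks, _ = simulate_dataset(scn, seed=10)
        assert cohort.y.sum() == 100 and (1 - cohort.y).sum() == 100
        assert len(blocks) == 4 and blocks[0].m.shape == (200, 11)
        cohort2, blocks2, _ = simulate_dataset(scn, seed=10)
        assert np.array_equal(cohort.y, cohort2.y)
        assert np.array_equal(blocks[2].m, blocks2[2].m)

    def test_scenario_from_yaml_file(self, tmp_path):
        f = tmp_path / "scn.yaml"
        f.write_text("j_genes: 7\nkappa: 0.5\nmodel_mix: [M, MGC]\n")
        scn = SimScenario.from_file(f)
        assert scn.j_genes == 7 and scn.kappa == 0.5
        assert scn.mix_models() == (DiseaseModel.M, DiseaseModel.MGC)
        bad = tmp_path / "bad.yaml"
        bad.write_text("j_genes: 7\nnot_a_field: 1\n")
        with pytest.raises(ValueError, match="unknown scenario"):
            SimScenario.from_file(bad)

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            SimScenario(signal_density=0.0)
        with pytest.raises(ValueError):
            SimScenario(n_cases=400, n_controls=400)
        with pytest.raises(ValueError):
            SimScenario(rho_between_meth=0.9, rho_within=0.8)


class TestStudy:
    def test_alpha_one_rejects_everything(self):
        scn = SimScenario(j_genes=2, kappa=0.0)
        tab = run_size_power_study(scn, n_reps=2, alpha=1.0,
                                   tests=("itegs-M",), methods=("davies",),
                                   seed=1)
        assert (tab["rate"] == 1.0).all()

    def test_study_is_deterministic_and_collects_pvalues(self):
        scn = SimScenario(j_genes=2, kappa=0.0)
        kw = dict(n_reps=3, tests=("itegs-MG", "inote-uni"),
                  methods=("davies",), b=120, seed=4, collect_pvalues=True)
        t1 = run_size_power_study(scn, **kw)
        t2 = run_size_power_study(scn, **kw)
        assert t1.attrs["pvalues"].equals(t2.attrs["pvalues"])
        assert len(t1.attrs["pvalues"]) == 3
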