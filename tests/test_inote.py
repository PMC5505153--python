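import numpy as np
import pytest
from scipy.stats import chi2

from inote.core_data import DiseaseModel, MODEL_ORDER
from inote.gene_kernels import build_kernel
from inote.inote import _min_over_models, inote_chi, inote_test, inote_uni, min_p_transform
from inote.itegs import itegs_test
from inote.null_dist import PerturbationEngine, empirical_p, perturb_q

from conftest import make_block


class TestMinPTransform:
    def test_frozen_quantiles(self):
        assert min_p_transform(1.0) == 0.0
        assert min_p_transform(0.05) == pytest.approx(3.8415, abs=5e-5)
        assert min_p_transform(0.5) == pytest.approx(0.4549, abs=5e-5)

    def test_round_trip(self):
        for p in (1e-6, 0.01, 0.3, 0.97, 1.0):
            assert chi2.sf(min_p_transform(p), 1) == pytest.approx(p, abs=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            min_p_transform(0.0)

    def test_tie_break_uses_fixed_model_order(self):
        vals = {m: 0.25 for m in MODEL_ORDER}
        _, model = _min_over_models(vals)
        assert model is DiseaseModel.M


def _reference_omnibus(blocks, null, engine):
    """Literal double-loop transcription of the two omnibus algorithms.

    Deliberately naive: per gene and per model, rebuild the kernel test,
    perturb it, and compute every p-value with explicit counting loops.
    Serves as the independent oracle for the vectorised implementation.
    """
    b = engine.b
    per_gene = []
    for block in blocks:
        p_obs, p_draws, q_obs_map, q_null_map = {}, {}, {}, {}
        for model in MODEL_ORDER:
            if not model.compatible_with(block):
                continue
            kt = build_kernel(block, null, model, compute_eigvals=False)
            q_null = perturb_q(kt, engine, null)
            p_obs[model] = sum(qn > kt.q_obs for qn in q_null) / b
            p_draws[model] = np.array(
                [sum(qo >= qb for qo in q_null) / b for qb in q_null]
            )
            q_obs_map[model], q_null_map[model] = kt.q_obs, q_null
        per_gene.append((p_obs, p_draws, q_obs_map, q_null_map))

    # chi branch
    t_obs, t_null = 0.0, np.zeros(b)
    for p_obs, p_draws, _, _ in per_gene:
        p_min = min(p_obs.values())
        t_obs += chi2.isf(p_min, 1)
        t_null += chi2.isf(np.minimum.reduce(list(p_draws.values())), 1)
    p_chi = (1 + sum(tn >= t_obs for tn in t_null)) / (b + 1)

    # uni branch: pooled Q per model with w_j = 1/SD(Q_j)
    p_net, p_net_draws = {}, {}
    for model in MODEL_ORDER:
        usable = [(blk, g) for blk, g in zip(blocks, per_gene) if model in g[2]]
        if not usable:
            continue
        q_tot, q_tot_null = 0.0, np.zeros(b)
        for blk, (_, _, q_obs_map, q_null_map) in usable:
            kt = build_kernel(blk, null, model, compute_eigvals=False)
            z = null.projected_half(kt.v_matrix)
            sd = np.sqrt(2.0 * np.sum((z.T @ z) ** 2)) / null.n
            q_tot += q_obs_map[model] / sd
            q_tot_null += q_null_map[model] / sd
        p_net[model] = sum(qn > q_tot for qn in q_tot_null) / b
        p_net_draws[model] = np.array(
            [sum(q2 >= q1 for q2 in q_tot_null) / b for q1 in q_tot_null]
        )
    p_min_obs = min(p_net.values())
    mins = np.minimum.reduce(list(p_net_draws.values()))
    p_uni = (1 + sum(mn <= p_min_obs for mn in mins)) / (b + 1)
    return p_chi, p_uni, t_obs


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_double_loop_reference(null60, seed):
    """Vectorised omnibus p-values equal the literal algorithm transcription."""
    rng_blocks = [make_block(n=60, p=p, seed=seed * 10 + k, gene_id=f"g{k}")
                  for k, p in enumerate((3, 2, 4))]
    engine = PerturbationEngine.create(60, b=150, seed=seed + 100)
    res = inote_test(rng_blocks, null60, engine)
    p_chi, p_uni, t_obs = _reference_omnibus(rng_blocks, null60, engine)
    assert res.p_inote_chi == pytest.approx(p_chi, abs=1e-12)
    assert res.p_inote_uni == pytest.approx(p_uni, abs=1e-12)
    assert res.t_net_obs == pytest.approx(t_obs, rel=1e-10)


def test_single_gene_single_model_reduces_to_perturbation_p(null60):
    """A one-gene set with methylation only: both omnibus tests collapse to
    that gene's model-M perturbation p within add-one resolution."""
    block = make_block(n=60, p=3, seed=4, with_g=False)
    engine = PerturbationEngine.create(60, b=400, seed=3)
    res = inote_test([block], null60, engine)
    kt = build_kernel(block, null60, DiseaseModel.M, compute_eigvals=False)
    p_ref = empirical_p(kt.q_obs, perturb_q(kt, engine, null60))
    assert abs(res.p_inote_chi - p_ref) <= 2 / (engine.b + 1)
    assert abs(res.p_inote_uni - p_ref) <= 2 / (engine.b + 1)
    assert res.selected_model is DiseaseModel.M


def test_gene_order_invariance(null60, blocks3):
    engine = PerturbationEngine.create(60, b=300, seed=8)
    res = inote_test(blocks3, null60, engine)
    rev = inote_test(blocks3[::-1], null60, engine)
    assert rev.p_inote_chi == res.p_inote_chi
    assert rev.p_inote_uni == res.p_inote_uni


def test_chi_and_uni_wrappers_agree_with_joint_run(null60, blocks3):
    engine = PerturbationEngine.create(60, b=200, seed=9)
    joint = inote_test(blocks3, null60, engine)
    assert inote_chi(blocks3, null60, engine).p_inote_chi == joint.p_inote_chi
    assert inote_uni(blocks3, null60, engine).p_inote_uni == joint.p_inote_uni


def test_add_one_floor_respected(null60):
    """Omnibus p-values never fall below 1/(B+1)."""
    rng = np.random.default_rng(0)
    # inject a strong signal so the observed statistic beats every draw
    y_signal = null60.residuals + 0.0  # use residuals as fake association
    block = make_block(n=60, p=3, seed=6)
    block.g = y_signal * 3 + rng.standard_normal(60) * 0.1
    block.c = block.m * block.g[:, None]
    engine = PerturbationEngine.create(60, b=200, seed=11)
    res = inote_test([block], null60, engine)
    assert res.p_inote_chi >= 1 / (engine.b + 1)
    assert res.p_inote_uni >= 1 / (engine.b + 1)
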