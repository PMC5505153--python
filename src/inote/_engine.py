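"""Shared gene-set computation engine.

One pass over the genes of a set produces everything the set-level tests
need: per-gene weighted designs and observed component scores, analytic
SDs for the gene weights ``w_j``, pooled mixture spectra for the
Davies/Satterthwaite routes, and (when an engine is supplied) the per-gene
perturbed component matrices from which every model's perturbation sample
is obtained by slicing rows. The public modules :mod:`inote.itegs` and
:mod:`inote.inote` are thin wrappers over :func:`prepare_genes` /
:func:`pooled_stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_data import DiseaseModel, GeneBlock, MODEL_ORDER
from .gene_kernels import ScoreComponents, score_components
from .null_dist import PerturbationEngine, perturb_components
from .null_model import NullModel

logger = logging.getLogger(__name__)


@dataclass
class GeneComputation:
    """Per-gene material shared by all set-level tests."""

    block: GeneBlock
    scores: ScoreComponents
    v_full: np.ndarray = field(repr=False)       # n x q stacked weighted design
    rows: dict[DiseaseModel, np.ndarray] = field(default_factory=dict, repr=False)
    t_obs: np.ndarray = field(default=None, repr=False)   # V'r, length q
    z_full: np.ndarray = field(default=None, repr=False)  # (I-H)W^{1/2}V
    q_obs: dict[DiseaseModel, float] = field(default_factory=dict)
    sd_q: dict[DiseaseModel, float] = field(default_factory=dict)
    t_pert: np.ndarray | None = field(default=None, repr=False)  # q x B

    @property
    def gene_id(self) -> str:
        return self.block.gene_id

    def models(self) -> list[DiseaseModel]:
        return [m for m in MODEL_ORDER if m in self.rows]

    def q_pert(self, model: DiseaseModel) -> np.ndarray:
        """Perturbation sample of this gene's Q under ``model``."""
        n = self.v_full.shape[0]
        return (self.t_pert[self.rows[model]] ** 2).sum(axis=0) / n


def _layout(block: GeneBlock, scores: ScoreComponents) -> tuple[np.ndarray, dict]:
    """Stacked weighted design over all available components + model row maps."""
    cols: list[np.ndarray] = []
    idx_m = idx_g = idx_c = None
    pos = 0
    if block.m is not None:
        cols.append(np.sqrt(scores.a1) * block.m)
        idx_m = np.arange(pos, pos + block.p)
        pos += block.p
    if block.g is not None:
        cols.append(np.sqrt(scores.a2) * block.g[:, None])
        idx_g = np.arange(pos, pos + 1)
        pos += 1
    if block.c is not None:
        cols.append(np.sqrt(scores.a3) * block.c)
        idx_c = np.arange(pos, pos + block.p)
        pos += 1
    v = np.hstack(cols)
    rows: dict[DiseaseModel, np.ndarray] = {}
    if idx_m is not None:
        rows[DiseaseModel.M] = idx_m
    if idx_g is not None:
        rows[DiseaseModel.G] = idx_g
    if idx_m is not None and idx_g is not None:
        rows[DiseaseModel.MG] = np.concatenate([idx_m, idx_g])
        if idx_c is not None:
            rows[DiseaseModel.MGC] = np.concatenate([idx_m, idx_g, idx_c])
    return v, rows


def prepare_genes(
    blocks: list[GeneBlock],
    null: NullModel,
    weight_method: str = "analytic",
    engine: PerturbationEngine | None = None,
    perturb: bool = False,
) -> list[GeneComputation]:
    """Run the per-gene pass: scores, weights, projections, perturbations."""
    genes: list[GeneComputation] = []
    n = null.n
    for block in blocks:
        scores = score_components(block, null, weight_method=weight_method,
                                  engine=engine)
        v, rows = _layout(block, scores)
        gc = GeneComputation(block=block, scores=scores, v_full=v, rows=rows)
        gc.t_obs = v.T @ null.residuals
        gc.z_full = null.projected_half(v)
        gram = gc.z_full.T @ gc.z_full
        for model, ridx in rows.items():
            gc.q_obs[model] = float((gc.t_obs[ridx] ** 2).sum()) / n
            sub = gram[np.ix_(ridx, ridx)]
            # SD(Q_j) = sqrt(2 tr((P0 K_j)^2)) / n with K_j = V V' restricted
            gc.sd_q[model] = float(np.sqrt(2.0 * np.sum(sub**2)) / n)
        if perturb:
            if engine is None:
                raise ValueError("perturbation requested without an engine")
            gc.t_pert = perturb_components(v, engine, null)
            if weight_method == "perturbation":
                # gene weights from the empirical SD of the perturbed Q,
                # mirroring the empirical route for the a-weights
                for model in rows:
                    gc.sd_q[model] = float(np.std(gc.q_pert(model), ddof=1))
        genes.append(gc)
    return genes


@dataclass
class PooledModel:
    """Set-level quantities for one uniform disease model."""

    model: DiseaseModel
    gene_ids: list[str]
    w: np.ndarray
    q_net_obs: float
    lambda_net: np.ndarray | None = None
    q_net_null: np.ndarray | None = None


def pooled_stats(
    genes: list[GeneComputation],
    null: NullModel,
    model: DiseaseModel,
    need_eig: bool = False,
    need_pert: bool = False,
) -> PooledModel | None:
    """Pool compatible genes under one uniform model.

    Gene weights are ``w_j = 1 / SD(Q_j)``; the pooled statistic is
    ``Q_Net = sum_j w_j Q_j = n^{-1} r' (sum_j w_j K_j) r``. Returns ``None``
    when no gene supports the model (the caller reports it untestable).
    """
    usable = [g for g in genes if model in g.rows]
    skipped = len(genes) - len(usable)
    if skipped:
        logger.info("model %s: dropped %d incompatible gene(s)", model.value, skipped)
    if not usable:
        return None
    w = np.array([1.0 / g.sd_q[model] for g in usable])
    q_net = float(sum(wi * g.q_obs[model] for wi, g in zip(w, usable)))
    out = PooledModel(model=model, gene_ids=[g.gene_id for g in usable],
                      w=w, q_net_obs=q_net)
    if need_eig:
        n = null.n
        acc = np.zeros((n, n))
        for wi, g in zip(w, usable):
            zj = g.z_full[:, g.rows[model]]
            acc += wi * (zj @ zj.T)
        lam = np.linalg.eigvalsh(acc / n)
        from .null_dist import _clip_eigvals

        out.lambda_net = _clip_eigvals(lam)[::-1].copy()
    if need_pert:
        qn = np.zeros(usable[0].t_pert.shape[1])
        for wi, g in zip(w, usable):
            qn += wi * g.q_pert(model)
        out.q_net_null = qn
    return out
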