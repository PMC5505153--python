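"""iTEGS: integrated total effect of a gene set under one uniform model.

The gene-set statistic pools the single-gene kernels::

    Q_Net = sum_j w_j Q_j = n^{-1} r' (w_1 K_1 + ... + w_J K_J) r

with gene weights ``w_j = 1 / SD(Q_j)`` chosen to put the per-gene
statistics on a common scale, and every gene tested under the same disease
model (M, G, MG or MGC). The expression-only specification (model G)
coincides with the classical single-platform total-effect gene-set test
with working independence among genes; the integrated models extend it
with the methylation and interaction kernels.

P-values come from :mod:`inote.null_dist` by any of the Satterthwaite,
Davies, or perturbation routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._engine import pooled_stats, prepare_genes
from .core_data import DiseaseModel, GeneBlock
from .null_dist import (
    PerturbationEngine,
    PValueTriple,
    davies_p,
    empirical_p,
    satterthwaite_p,
)
from .null_model import NullModel

logger = logging.getLogger(__name__)

__all__ = ["GeneSetKernel", "itegs_test"]

_METHODS = ("satterthwaite", "davies", "perturbation")


@dataclass
class GeneSetKernel:
    """Result of one iTEGS test.

    ``untestable`` is set (with everything else empty) when no gene in the
    set carries the data the requested model needs.
    """

    model: DiseaseModel
    q_net_obs: float | None = None
    w: np.ndarray | None = None
    gene_ids: list[str] = field(default_factory=list)
    lambda_net: np.ndarray | None = field(default=None, repr=False)
    q_net_null: np.ndarray | None = field(default=None, repr=False)
    pvalues: PValueTriple = field(default_factory=PValueTriple)
    n_genes_total: int = 0
    n_genes_tested: int = 0
    untestable: bool = False


def itegs_test(
    blocks: list[GeneBlock],
    null: NullModel,
    model: DiseaseModel,
    engine: PerturbationEngine | None = None,
    methods: tuple[str, ...] = ("davies",),
    weight_method: str = "analytic",
) -> GeneSetKernel:
    """Test the total effect of a gene set under one uniform disease model.

    Parameters
    ----------
    blocks : list of GeneBlock
        Per-gene data; genes incompatible with ``model`` are dropped with a
        logged reason and do not contribute weight.
    null : NullModel
        Fitted covariates-only logistic null.
    model : DiseaseModel
        Uniform disease model for every gene in the set.
    engine : PerturbationEngine, optional
        Required when ``"perturbation"`` is among ``methods``.
    methods : tuple of str
        Any of ``"satterthwaite"``, ``"davies"``, ``"perturbation"``.
    weight_method : {"analytic", "perturbation"}
        How the component weights a1-a3 and gene SDs are computed.

    Returns
    -------
    GeneSetKernel
        Pooled statistic, gene weights, mixture spectrum and requested
        p-values; ``untestable`` if no gene supports the model.
    """
    for m in methods:
        if m not in _METHODS:
            raise ValueError(f"unknown p-value method {m!r}")
    need_pert = "perturbation" in methods
    if need_pert and engine is None:
        raise ValueError("perturbation p-values require a PerturbationEngine")
    need_eig = ("davies" in methods) or ("satterthwaite" in methods)

    genes = prepare_genes(blocks, null, weight_method=weight_method,
                          engine=engine, perturb=need_pert)
    pooled = pooled_stats(genes, null, model, need_eig=need_eig,
                          need_pert=need_pert)
    if pooled is None:
        logger.warning("gene set untestable under model %s", model.value)
        return GeneSetKernel(model=model, n_genes_total=len(blocks),
                             untestable=True)

    result = GeneSetKernel(
        model=model,
        q_net_obs=pooled.q_net_obs,
        w=pooled.w,
        gene_ids=pooled.gene_ids,
        lambda_net=pooled.lambda_net,
        q_net_null=pooled.q_net_null,
        n_genes_total=len(blocks),
        n_genes_tested=len(pooled.gene_ids),
    )
    if "satterthwaite" in methods:
        result.pvalues.satterthwaite = satterthwaite_p(pooled.q_net_obs,
                                                       pooled.lambda_net)
    if "davies" in methods:
        result.pvalues.davies = davies_p(pooled.q_net_obs, pooled.lambda_net)
    if need_pert:
        result.pvalues.perturbation = empirical_p(pooled.q_net_obs,
                                                  pooled.q_net_null)
        result.pvalues.b = engine.b
    return result
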