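"""Single-gene score statistics, component weights and kernel tests.

For one gene with methylation matrix ``M`` (n x p), expression ``G`` and
interaction matrix ``C = G * M`` columnwise, the component score statistics
against the covariates-only null are::

    U_tauM  = r' M M' r        (variance component for the CpG block)
    U_betaG = G' r             (scalar score for expression)
    U_tauC  = r' C C' r        (variance component for the interactions)

with ``r = Y - mu0``. The single-gene test statistics are weighted sums,
e.g. ``Q_MGC = n^{-1} (a1 U_tauM + a2 U_betaG^2 + a3 U_tauC)``, where the
weights are the inverse square roots of the null variances of the three
summands so the components enter on comparable scales. Each Q is equally a
kernel quadratic form ``n^{-1} r' K r`` with
``K = a1 MM' + a2 GG' + a3 CC'`` restricted to the disease model, i.e.
``K = V V'`` for the stacked weighted design
``V = [sqrt(a1) M, sqrt(a2) G, sqrt(a3) C]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import DiseaseModel, GeneBlock
from .null_dist import PerturbationEngine, mixture_weights_from_design, perturb_components
from .null_model import NullModel

__all__ = ["ScoreComponents", "KernelTest", "score_components", "build_kernel"]


@dataclass
class ScoreComponents:
    """Component score statistics and their scale weights for one gene.

    Fields are ``None`` when the corresponding platform is absent. The
    weights ``a1``/``a2``/``a3`` multiply ``U_tauM``, ``U_betaG**2`` and
    ``U_tauC`` respectively and equal the inverse square roots of the
    analytic null variances (or perturbation-sample variances on request).
    """

    u_tau_m: float | None = None
    u_beta_g: float | None = None
    u_tau_c: float | None = None
    a1: float | None = None
    a2: float | None = None
    a3: float | None = None


def _check_nonconstant(arr: np.ndarray, what: str, gene: str) -> None:
    if arr.ndim == 1:
        arr = arr[:, None]
    spans = arr.max(axis=0) - arr.min(axis=0)
    bad = np.nonzero(spans == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"gene {gene}: zero-variance {what} column(s) {bad.tolist()}; "
            "component weight undefined"
        )


def _analytic_weights(
    block: GeneBlock, null: NullModel
) -> tuple[float | None, float | None, float | None]:
    """Inverse-sqrt null variances of (U_tauM, U_betaG^2, U_tauC).

    With ``P0`` the null residual covariance: ``Var(U_tauM) = 2 tr((P0 MM')^2)
    = 2 ||M'P0M||_F^2`` (and likewise for C); ``U_betaG^2`` is asymptotically
    ``(G'P0G) chi2_1`` so ``Var = 2 (G'P0G)^2``.
    """
    a1 = a2 = a3 = None
    if block.m is not None:
        zm = null.projected_half(block.m)
        a1 = 1.0 / np.sqrt(2.0 * np.sum((zm.T @ zm) ** 2))
    if block.g is not None:
        zg = null.projected_half(block.g[:, None])
        a2 = 1.0 / (np.sqrt(2.0) * float((zg * zg).sum()))
    if block.c is not None:
        zc = null.projected_half(block.c)
        a3 = 1.0 / np.sqrt(2.0 * np.sum((zc.T @ zc) ** 2))
    return a1, a2, a3


def _perturbation_weights(
    block: GeneBlock, null: NullModel, engine: PerturbationEngine
) -> tuple[float | None, float | None, float | None]:
    """Weights from the empirical SD of unweighted perturbed components."""
    a1 = a2 = a3 = None
    if block.m is not None:
        t = perturb_components(block.m, engine, null)
        a1 = 1.0 / float(np.std((t**2).sum(axis=0), ddof=1))
    if block.g is not None:
        t = perturb_components(block.g[:, None], engine, null)
        a2 = 1.0 / float(np.std(t[0] ** 2, ddof=1))
    if block.c is not None:
        t = perturb_components(block.c, engine, null)
        a3 = 1.0 / float(np.std((t**2).sum(axis=0), ddof=1))
    return a1, a2, a3


def score_components(
    block: GeneBlock,
    null: NullModel,
    weight_method: str = "analytic",
    engine: PerturbationEngine | None = None,
) -> ScoreComponents:
    """Compute the per-gene score statistics and their scale weights.

    Parameters
    ----------
    block : GeneBlock
        Molecular data for one gene; absent platforms yield ``None`` fields.
    null : NullModel
        Fitted covariates-only logistic null.
    weight_method : {"analytic", "perturbation"}
        Analytic trace-based null variances (default) or the empirical SD of
        the unweighted perturbation samples (for sensitivity checks).
    engine : PerturbationEngine, optional
        Required for ``weight_method="perturbation"``.
    """
    r = null.residuals
    out = ScoreComponents()
    if block.m is not None:
        _check_nonconstant(block.m, "methylation", block.gene_id)
        mtr = block.m.T @ r
        out.u_tau_m = float(mtr @ mtr)
    if block.g is not None:
        _check_nonconstant(block.g, "expression", block.gene_id)
        out.u_beta_g = float(block.g @ r)
    if block.c is not None:
        _check_nonconstant(block.c, "interaction", block.gene_id)
        ctr = block.c.T @ r
        out.u_tau_c = float(ctr @ ctr)

    if weight_method == "analytic":
        out.a1, out.a2, out.a3 = _analytic_weights(block, null)
    elif weight_method == "perturbation":
        if engine is None:
            raise ValueError("perturbation weights need a PerturbationEngine")
        out.a1, out.a2, out.a3 = _perturbation_weights(block, null, engine)
    else:
        raise ValueError(f"unknown weight_method {weight_method!r}")
    return out


@dataclass
class KernelTest:
    """A Q statistic with the material needed for its null distribution.

    ``v_matrix`` stacks the weight-scaled component designs
    (``sqrt(a1) M | sqrt(a2) G | sqrt(a3) C`` restricted to the model), so
    that ``kernel = v_matrix v_matrix'`` and
    ``q_obs = n^{-1} r' kernel r``. ``eigvals`` are the mixture weights of
    the asymptotic null (computed on construction by default).
    """

    model: DiseaseModel
    q_obs: float
    v_matrix: np.ndarray = field(repr=False)
    eigvals: np.ndarray | None = field(default=None, repr=False)
    gene_id: str = ""
    scores: ScoreComponents | None = field(default=None, repr=False)

    @property
    def kernel(self) -> np.ndarray:
        """Dense n x n kernel matrix (materialised on demand)."""
        return self.v_matrix @ self.v_matrix.T


def weighted_design(block: GeneBlock, scores: ScoreComponents,
                    model: DiseaseModel) -> np.ndarray:
    """Stack the weight-scaled columns of the components ``model`` uses."""
    parts = []
    if model.needs_m:
        parts.append(np.sqrt(scores.a1) * block.m)
    if model.needs_g:
        parts.append(np.sqrt(scores.a2) * block.g[:, None])
    if model is DiseaseModel.MGC:
        parts.append(np.sqrt(scores.a3) * block.c)
    return np.hstack(parts)


def build_kernel(
    block: GeneBlock,
    null: NullModel,
    model: DiseaseModel,
    scores: ScoreComponents | None = None,
    compute_eigvals: bool = True,
    weight_method: str = "analytic",
    engine: PerturbationEngine | None = None,
) -> KernelTest:
    """Assemble the single-gene kernel test for one disease model.

    Raises ``ValueError`` when the block lacks a platform the model needs
    or contains a zero-variance column (propagated from
    :func:`score_components`).
    """
    if not model.compatible_with(block):
        raise ValueError(
            f"gene {block.gene_id}: model {model.value} incompatible with "
            "available data"
        )
    if scores is None:
        scores = score_components(block, null, weight_method=weight_method,
                                  engine=engine)
    v = weighted_design(block, scores, model)
    n = null.n
    vr = v.T @ null.residuals
    q_obs = float(vr @ vr) / n
    eig = mixture_weights_from_design(v, null) if compute_eigvals else None
    return KernelTest(model=model, q_obs=q_obs, v_matrix=v, eigvals=eig,
                      gene_id=block.gene_id, scores=scores)
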