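"""Null distributions and p-values for kernel quadratic-form statistics.

Every Q statistic in this package has the form ``Q = n^{-1} r' K r`` with
``r = Y - mu0`` the null-model residuals and ``K = V V'`` a weighted
positive-semidefinite kernel. Asymptotically ``Q`` follows a mixture of
chi-square distributions ``sum_l lambda_l chi2_1`` whose weights are the
eigenvalues of ``n^{-1} V' P0 V``, with ``P0 = W - WX(X'WX)^{-1}X'W`` the
null covariance of the residuals (equivalently, of ``A D A'`` built from
the joint score covariance ``D = n^{-1} U'WU``, ``U_i = (X_i', V_i')`` and
``A = [-D_XV' D_XX^{-1}, I]``).

Three p-value routes are provided:

* :func:`satterthwaite_p` — two-moment scaled chi-square approximation;
* :func:`davies_p` — numerical inversion of the mixture characteristic
  function (exact up to quadrature accuracy);
* perturbation — resample realisations of the asymptotic null by
  multiplying per-subject score contributions with shared standard normal
  draws (:class:`PerturbationEngine`, :func:`perturb_q`,
  :func:`empirical_p`).

The perturbation normals are drawn once per analysis and reused for every
gene and every disease model; the omnibus min-p procedures are only valid
with common draws, so sharing is enforced structurally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationEngine",
    "PValueTriple",
    "mixture_weights",
    "mixture_weights_from_design",
    "satterthwaite_p",
    "davies_p",
    "perturb_q",
    "perturb_components",
    "empirical_p",
    "proportion_p",
    "ranked_p",
]

#: eigenvalues below this fraction of the largest are treated as zero
_EIG_RTOL = 1e-12


@dataclass
class PValueTriple:
    """P-values for one statistic by the three available routes."""

    satterthwaite: float | None = None
    davies: float | None = None
    perturbation: float | None = None
    b: int | None = None

    def best(self) -> float:
        """Preferred p-value: Davies, else perturbation, else Satterthwaite."""
        for p in (self.davies, self.perturbation, self.satterthwaite):
            if p is not None:
                return p
        raise ValueError("no p-value computed")


@dataclass
class PerturbationEngine:
    """Shared standard-normal draws for the perturbation procedure.

    One engine per analysis: the same ``n x B`` matrix of N(0,1) draws is
    reused across all genes and disease models so that the b-th perturbed
    realisation of every statistic comes from the same random multipliers
    (required for jointly valid min-p omnibus nulls).
    """

    b: int
    seed: int
    normals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def create(cls, n: int, b: int = 1000, seed: int = 0) -> "PerturbationEngine":
        if b < 100:
            logger.warning("B=%d perturbations gives poor p-value resolution", b)
        rng = np.random.default_rng(seed)
        return cls(b=b, seed=seed, normals=rng.standard_normal((n, b)))

    def scores(self, null) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(S, X'S)`` with ``S = diag(r) N`` for a null model.

        Cached per null model: ``S[i, b] = (Y_i - mu0_i) N_i^{(b)}`` and its
        covariate projection are shared by every test in the analysis.
        """
        key = id(null)
        if key not in self._cache:
            if null.n != self.normals.shape[0]:
                raise ValueError(
                    f"engine drawn for n={self.normals.shape[0]}, null has n={null.n}"
                )
            s = self.normals * null.residuals[:, None]
            self._cache = {key: (s, null.x.T @ s)}
        return self._cache[key]


def _clip_eigvals(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    top = lam.max(initial=0.0)
    if (lam < -1e-8 * max(top, 1.0)).any():
        logger.warning("clipping negative mixture eigenvalues (min %.3e)", lam.min())
    lam = np.clip(lam, 0.0, None)
    return lam[lam > _EIG_RTOL * max(top, 1.0)]


def mixture_weights_from_design(v: np.ndarray, null) -> np.ndarray:
    """Mixture weights for ``Q = n^{-1} r'VV'r`` directly from the design.

    Computes the nonzero spectrum of ``n^{-1} V'P0V`` via ``Z = (I-H)W^{1/2}V``
    using whichever Gram matrix (``Z'Z`` or ``ZZ'``) is smaller.
    """
    z = null.projected_half(v)
    n, q = z.shape
    gram = (z.T @ z if q <= n else z @ z.T) / null.n
    lam = np.linalg.eigvalsh(gram)
    return _clip_eigvals(lam)[::-1].copy()


def mixture_weights(test, null) -> np.ndarray:
    """Mixture weights of the null distribution of a kernel test.

    Equivalent to the eigenvalues of ``A D A'`` in the score-resampling
    construction; see the module docstring.
    """
    return mixture_weights_from_design(test.v_matrix, null)


def satterthwaite_p(q_obs: float, lam: np.ndarray) -> float:
    """Two-moment (Satterthwaite) scaled chi-square tail probability."""
    lam = np.asarray(lam, dtype=float)
    s1 = lam.sum()
    s2 = (lam**2).sum()
    if s1 <= 0 or s2 <= 0:
        raise ValueError("all mixture weights are zero")
    kappa = s2 / s1
    nu = s1**2 / s2
    return float(chi2.sf(q_obs / kappa, nu))


def _imhof_integrand(u: float, lam: np.ndarray, q: float) -> float:
    lu = lam * u
    theta = 0.5 * (np.sum(np.arctan(lu)) - q * u)
    log_rho = 0.25 * np.sum(np.log1p(lu**2))
    return float(np.sin(theta) * np.exp(-log_rho) / u)


def _phase_amp(u: float, lam: np.ndarray) -> tuple[float, float]:
    """Smooth phase ``phi(u)`` and amplitude ``1/(u rho(u))`` of the
    inversion integrand, with the oscillatory ``-qu/2`` part factored out."""
    lu = lam * u
    phi = 0.5 * np.sum(np.arctan(lu))
    amp = np.exp(-0.25 * np.sum(np.log1p(lu**2))) / u
    return phi, amp


def davies_p(q_obs: float, lam: np.ndarray, acc: float = 1e-6) -> float:
    """Mixture-of-chi-square tail probability by characteristic-function
    inversion.

    Numerically inverts the characteristic function of
    ``sum_l lambda_l chi2_1`` (the Imhof integral form):
    ``P(Q > q) = 1/2 + (1/pi) int_0^inf sin(theta(u)) / (u rho(u)) du``.
    The head of the integral (at most one oscillation) is handled by
    adaptive quadrature; the oscillatory tail is decomposed as
    ``sin(theta) = sin(phi)cos(qu/2) - cos(phi)sin(qu/2)`` with ``phi``
    smooth and bounded, and each term integrated with Fourier-weighted
    quadrature, which is robust however slowly the envelope decays. On
    quadrature failure the Satterthwaite approximation is returned with a
    logged warning. The result is clipped into ``(1e-12, 1]``.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all mixture weights are zero")
    if q_obs <= 0:
        return 1.0
    q = float(q_obs)
    half_q = q / 2.0
    a = 2.0 * np.pi / q  # one oscillation period of the e^{-iqu/2} factor

    def f_cos(u: float) -> float:
        phi, amp = _phase_amp(u, lam)
        return float(np.sin(phi) * amp)

    def f_sin(u: float) -> float:
        phi, amp = _phase_amp(u, lam)
        return float(-np.cos(phi) * amp)

    try:
        with np.errstate(over="ignore"):
            head, e0 = integrate.quad(_imhof_integrand, 0.0, a,
                                      args=(lam, q), epsabs=acc, epsrel=acc,
                                      limit=200)
            tail_c, e1 = integrate.quad(f_cos, a, np.inf, weight="cos",
                                        wvar=half_q, epsabs=acc, limit=500)
            tail_s, e2 = integrate.quad(f_sin, a, np.inf, weight="sin",
                                        wvar=half_q, epsabs=acc, limit=500)
        p = 0.5 + (head + tail_c + tail_s) / np.pi
        err = e0 + e1 + e2
        if not np.isfinite(p) or err > 1e-3 or p < -1e-3 or p > 1 + 1e-3:
            raise RuntimeError(f"inversion unreliable (p={p}, err={err})")
    except Exception as exc:  # quadrature failure -> two-moment fallback
        logger.warning("characteristic-function inversion failed (%s); "
                       "falling back to Satterthwaite", exc)
        return satterthwaite_p(q_obs, lam)
    return float(np.clip(p, 1e-12, 1.0))


def perturb_components(v: np.ndarray, engine: PerturbationEngine, null) -> np.ndarray:
    """Corrected perturbed score components, shape ``(q, B)``.

    Column ``b`` holds ``sqrt(n) A eps_hat^{(b)}`` restricted to the rows of
    design ``v``: the perturbed realisation of ``V'r`` with the covariate
    estimation effect removed. Squared column sums divided by ``n`` give the
    perturbed Q statistics; callers may slice rows to obtain nested models.
    """
    s, xs = engine.scores(null)
    t = v.T @ s
    t -= null.correction_coef(v) @ xs
    return t


def perturb_q(test, engine: PerturbationEngine, null) -> np.ndarray:
    """Perturbation sample ``{Q_hat^{(b)}}`` of a kernel test statistic."""
    t = perturb_components(test.v_matrix, engine, null)
    return (t**2).sum(axis=0) / null.n


def empirical_p(q_obs: float, q_null: np.ndarray) -> float:
    """Add-one empirical tail probability.

    ``p = (1 + #{Q_hat^{(b)} >= q_obs}) / (B + 1)``; always positive, so
    min-p transforms stay finite.
    """
    q_null = np.asarray(q_null, dtype=float)
    if q_null.size < 1:
        raise ValueError("empty null sample")
    return float((1 + (q_null >= q_obs).sum()) / (q_null.size + 1))


def proportion_p(q_obs: float, q_null: np.ndarray) -> float:
    """Plain proportion of draws strictly exceeding the observed value.

    ``p = #{Q_hat^{(b)} > q_obs} / B``; zero when the observed statistic
    beats every draw. This is the tail-probability convention of the
    omnibus algorithms, where an observed minimum p of exactly zero is a
    meaningful "beyond resolution" outcome (it maps to an infinite
    chi-square quantile). Use :func:`empirical_p` wherever a strictly
    positive, reportable p-value is needed.
    """
    q_null = np.asarray(q_null, dtype=float)
    if q_null.size < 1:
        raise ValueError("empty null sample")
    return float((q_null > q_obs).sum() / q_null.size)


def ranked_p(q_null: np.ndarray) -> np.ndarray:
    """Tail probability of each draw within its own sample.

    Draw ``b`` receives ``#{b': Q^{(b')} >= Q^{(b)}} / B`` (the count
    includes ``b`` itself), yielding values on ``{1/B,...,1}`` at
    O(B log B); the per-draw analogue of :func:`proportion_p`, never zero.
    """
    q_null = np.asarray(q_null, dtype=float)
    b = q_null.size
    order = np.sort(q_null)
    cnt_ge = b - np.searchsorted(order, q_null, side="left")
    return cnt_ge / float(b)
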