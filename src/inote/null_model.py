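"""Covariates-only logistic null model.

All the Q statistics are score tests around the null fit
``logit P(Y_i = 1 | X_i) = X_i' beta_X``; the fitted means ``mu0``, the
residuals ``Y - mu0`` and the weight diagonal ``W = diag{mu0 (1 - mu0)}``
are the only quantities downstream modules need. The fit is plain IRLS
(Newton with step-halving on the deviance) run to a tight score-norm
tolerance, because the validity of the score statistics rests on the score
equations ``X'(Y - mu0) = 0`` holding essentially exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NullModel", "fit_null", "SeparationError", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; consider reducing covariates."""


class SeparationError(RuntimeError):
    """Fitted probabilities hit 0/1: quasi-separated design."""


@dataclass
class NullModel:
    """Fitted covariates-only logistic model and derived projection pieces."""

    beta_x_hat: np.ndarray
    mu0_hat: np.ndarray
    residuals: np.ndarray
    w_diag: np.ndarray
    x: np.ndarray
    _xtwx_inv: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._xtwx_inv is None:
            wx = self.x * self.w_diag[:, None]
            self._xtwx_inv = np.linalg.inv(self.x.T @ wx)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def projected_half(self, v: np.ndarray) -> np.ndarray:
        """Return ``Z`` with ``Z'Z = V' P0 V``.

        ``P0 = W - W X (X'WX)^{-1} X' W`` is the null covariance of the
        residual vector; ``Z = (I - H) W^{1/2} V`` with ``H`` the weighted
        hat matrix. Used for analytic variances and mixture weights.
        """
        v = np.atleast_2d(v.T).T if v.ndim == 1 else v
        sw = np.sqrt(self.w_diag)
        swv = v * sw[:, None]
        swx = self.x * sw[:, None]
        # H swv = swx (X'WX)^{-1} (swx' swv)
        return swv - swx @ (self._xtwx_inv @ (swx.T @ swv))

    def correction_coef(self, v: np.ndarray) -> np.ndarray:
        """Return ``(V'WX)(X'WX)^{-1}``, shape (q, r).

        This is ``D_VX D_XX^{-1}``: the coefficient that removes the
        covariate-estimation component from perturbed score realisations.
        """
        v = np.atleast_2d(v.T).T if v.ndim == 1 else v
        vwx = (v * self.w_diag[:, None]).T @ self.x
        return vwx @ self._xtwx_inv


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-300
    return -2.0 * float(y @ np.log(mu + eps) + (1 - y) @ np.log(1 - mu + eps))


def fit_null(cohort, tol: float = 1e-10, max_iter: int = 100) -> NullModel:
    """Fit the covariates-only logistic null by IRLS with step-halving.

    Parameters
    ----------
    cohort : Cohort
        Outcome and covariate design (intercept first).
    tol : float
        Convergence tolerance on the score norm ``max |X'(Y - mu0)|``.
    max_iter : int
        Maximum Newton iterations.

    Raises
    ------
    ConvergenceError
        If the score norm does not reach ``tol`` within ``max_iter``.
    SeparationError
        If any fitted probability leaves ``[1e-10, 1 - 1e-10]`` (the weight
        matrix would be numerically singular downstream).
    """
    y, x = cohort.y, cohort.x
    n, r = x.shape
    beta = np.zeros(r)
    beta[0] = np.log(y.mean() / (1.0 - y.mean()))  # start at marginal logit
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    dev = _deviance(y, mu)
    converged = False
    for _ in range(max_iter):
        score = x.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        xtwx = x.T @ (x * w[:, None])
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank guarded upstream
            raise ConvergenceError("singular information matrix") from exc
        # step-halving: back off until the deviance does not increase
        lam = 1.0
        for _half in range(30):
            beta_new = beta + lam * step
            mu_new = 1.0 / (1.0 + np.exp(-(x @ beta_new)))
            dev_new = _deviance(y, mu_new)
            if dev_new <= dev + 1e-12:
                break
            lam *= 0.5
        beta, mu, dev = beta_new, mu_new, dev_new
    else:
        score = x.T @ (y - mu)
        converged = np.max(np.abs(score)) < tol
    if not converged:
        raise ConvergenceError(
            "null logistic fit did not converge; reduce or rescale covariates"
        )
    if mu.min() < 1e-10 or mu.max() > 1.0 - 1e-10:
        raise SeparationError(
            "fitted probabilities at 0/1 indicate (quasi-)separation; "
            "reduce covariates"
        )
    return NullModel(
        beta_x_hat=beta,
        mu0_hat=mu,
        residuals=y - mu,
        w_diag=mu * (1.0 - mu),
        x=x,
    )
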