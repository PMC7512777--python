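"""Analytic selection-bias machinery.

When outcomes are missing not at random -- the outcome error is correlated
(correlation ``rho``) with the latent selection score -- the conditional
posterior of the regression function given the selected outcomes carries a
truncated-normal component.  Ignoring it (fitting a plain GP regression to
the selected data) biases the posterior mean of the regression function and
the marginal effect of any covariate appearing in both equations.  This
module provides:

* :func:`sample_selected_outcome` -- the two-stage stochastic representation of a
  selected observation, the module's master sampling oracle;
* :func:`selection_bias` -- the analytic posterior-mean gap between the
  selection-aware and selection-naive fits (normal-error case);
* :func:`marginal_effect_diff` -- the analytic gap in the marginal effect
  of a shared covariate;
* grid utilities exporting both as curves over (beta or alpha) x rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .smn import ErrorScale, MixingSpec, SelectionInterval
from .truncnorm import sample_lower_truncated

__all__ = [
    "BiasOperators",
    "sample_selected_outcome",
    "trunc_mean_xi",
    "selection_bias",
    "selection_bias_from_beta",
    "marginal_effect_diff",
    "bias_curve",
    "marginal_effect_curve",
    "intraclass_cov",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def _phi(x):
    return np.exp(-0.5 * np.asarray(x, float) ** 2) / _SQRT_2PI


def _hazard(x):
    """phi(x)/(1-Phi(x)), stable in the upper tail."""
    x = np.asarray(x, float)
    return np.exp(-0.5 * x * x - 0.5 * np.log(2.0 * np.pi) - log_ndtr(-x))


@dataclass
class BiasOperators:
    """Operators of the conditional-posterior stochastic representation.

    With ``H = K11 + delta*sigma2*I``: ``Omega1 = delta*sigma2*K11 H^{-1}``
    (the GP posterior covariance), ``Omega2 = (1-rho^2)I + rho^2
    Omega1/sigma2`` (the covariance of the truncated component), ``Gamma =
    -rho*Omega1/sigma`` (their coupling), ``theta1`` the selection-naive
    posterior mean and ``beta`` the truncation thresholds.
    """

    H: np.ndarray
    Omega1: np.ndarray
    Omega2: np.ndarray
    Gamma: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    beta: np.ndarray

    @classmethod
    def build(cls, y, K11, m1, scale: ErrorScale, alphas, delta: float = 1.0):
        y = np.asarray(y, float).reshape(-1)
        K11 = np.asarray(K11, float)
        m1 = np.asarray(m1, float).reshape(-1)
        alphas = np.broadcast_to(np.asarray(alphas, float), y.shape).astype(float)
        n1 = y.shape[0]
        sigma2, sigma, rho = scale.sigma2, scale.sigma, scale.rho
        H = K11 + delta * sigma2 * np.eye(n1)
        Hinv = np.linalg.inv(H)
        Omega1 = delta * sigma2 * (K11 @ Hinv)
        Omega1 = 0.5 * (Omega1 + Omega1.T)
        Omega2 = (1.0 - rho ** 2) * np.eye(n1) + rho ** 2 * Omega1 / sigma2
        Gamma = -rho * Omega1 / sigma
        theta1 = K11 @ (Hinv @ y) + delta * sigma2 * (Hinv @ m1)
        theta2 = rho * (y - m1) / sigma
        beta = (alphas - theta2) / np.sqrt(delta)
        return cls(H=H, Omega1=Omega1, Omega2=Omega2, Gamma=Gamma,
                   theta1=theta1, theta2=theta2, beta=beta)


def sample_selected_outcome(eta_i: float, scale: ErrorScale, C: SelectionInterval | float,
                  spec: MixingSpec | None, n_draws: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draws of a selected observation via the two-stage representation.

    ``y = eta + rho*sigma*Z_C + sigma*sqrt(1-rho^2)*U`` with, conditionally
    on ``omega ~ G``, ``U ~ N(0, delta(omega))`` and ``Z_C`` the
    ``N(0, delta(omega))`` law truncated to ``(alpha, inf)``.
    """
    spec = MixingSpec.degenerate() if spec is None else spec
    alpha = C.alpha if isinstance(C, SelectionInterval) else float(C)
    omega = spec.draw_omega(n_draws, rng)
    sd = np.sqrt(spec.delta_of(omega))
    z_c = sample_lower_truncated(0.0, sd, alpha, rng)
    u = sd * rng.standard_normal(n_draws)
    return (eta_i + scale.rho * scale.sigma * z_c
            + scale.sigma * np.sqrt(1.0 - scale.rho ** 2) * u)


def trunc_mean_xi(beta, omega2_diag):
    """Mean of a ``N(0, w*)`` variable truncated to ``(beta, inf)``:
    ``sqrt(w*) phi(beta/sqrt(w*)) / (1 - Phi(beta/sqrt(w*)))``.

    Strictly positive, increasing in ``beta`` and never below ``beta``.
    """
    beta = np.asarray(beta, float)
    w = np.asarray(omega2_diag, float)
    if (w <= 0).any():
        raise ValueError("truncation variances must be positive")
    s = np.sqrt(w)
    return s * _hazard(beta / s)


def selection_bias_from_beta(beta, K11, scale: ErrorScale) -> np.ndarray:
    """Posterior-mean gap for given truncation thresholds ``beta``.

    Derived from the stochastic representation of the conditional
    posterior: gap = Gamma Omega2*^{-1} xi =
    ``-rho*sigma * Omega1* [rho^2 Omega1* + sigma^2(1-rho^2) I]^{-1} xi``,
    with the starred operators evaluated at ``delta = 1`` (normal errors).
    Exactly zero at ``rho = 0``; componentwise sign opposite to ``rho``.
    """
    K11 = np.asarray(K11, float)
    n1 = K11.shape[0]
    beta = np.broadcast_to(np.asarray(beta, float), (n1,)).astype(float)
    sigma2, sigma, rho = scale.sigma2, scale.sigma, scale.rho
    if rho == 0.0:
        return np.zeros(n1)
    H = K11 + sigma2 * np.eye(n1)
    Omega1 = sigma2 * (K11 @ np.linalg.inv(H))
    Omega1 = 0.5 * (Omega1 + Omega1.T)
    Omega2 = (1.0 - rho ** 2) * np.eye(n1) + rho ** 2 * Omega1 / sigma2
    xi = trunc_mean_xi(beta, np.diag(Omega2))
    M = rho ** 2 * Omega1 + sigma2 * (1.0 - rho ** 2) * np.eye(n1)
    return -rho * sigma * (Omega1 @ np.linalg.solve(M, xi))


def selection_bias(y_obs, K11, m1, scale: ErrorScale, alphas) -> np.ndarray:
    """Gap between the selection-aware and selection-naive conditional
    posterior means of the regression function, for observed outcomes
    ``y_obs`` and selection thresholds ``alphas``."""
    ops = BiasOperators.build(y_obs, K11, m1, scale, alphas, delta=1.0)
    return selection_bias_from_beta(ops.beta, K11, scale)


def marginal_effect_diff(gamma_k: float, scale: ErrorScale,
                         alpha: float, spec: MixingSpec | None = None) -> float:
    """Difference in the marginal effect of a covariate shared by both
    equations, between the selection-aware and naive models.

    Obtained by differentiating
    ``E[y|s=1] = eta + rho*sigma*E_w[sqrt(delta) phi(a)] / Fbar`` (with
    ``a = alpha/sqrt(delta)``) with respect to the covariate:

        gamma_k*rho*sigma*( E_w[a phi(a)]/Fbar
                            - E_w[sqrt(delta) phi(a)] E_w[phi(a)/sqrt(delta)] / Fbar^2 )

    In the degenerate (normal) case this is ``gamma_k*rho*sigma*(b2 - b1^2)``
    with ``b1 = phi(alpha)/(1-Phi(alpha))`` and ``b2 = alpha*b1``.  Zero at
    ``rho = 0`` or ``gamma_k = 0``.
    """
    spec = MixingSpec.degenerate() if spec is None else spec
    rho, sigma = scale.rho, scale.sigma
    if rho == 0.0 or gamma_k == 0.0:
        return 0.0
    if spec.is_degenerate:
        lam = float(_hazard(alpha))
        return gamma_k * rho * sigma * (alpha * lam - lam * lam)
    delta, logw = spec._quad
    w = np.exp(logw)
    sd = np.sqrt(delta)
    a = alpha / sd
    phi_a = _phi(a)
    fbar = float(np.sum(w * np.exp(log_ndtr(-a))))
    t1 = float(np.sum(w * a * phi_a))
    t2 = float(np.sum(w * sd * phi_a))
    t3 = float(np.sum(w * phi_a / sd))
    return gamma_k * rho * sigma * (t1 / fbar - t2 * t3 / fbar ** 2)


# ---------------------------------------------------------------------------
# curve utilities (graphs of bias vs beta/alpha and rho)
# ---------------------------------------------------------------------------

def intraclass_cov(n1: int, a: float = 0.5, b: float = 0.5) -> np.ndarray:
    """Equicorrelated covariance ``a I + b 11'/n1``."""
    return a * np.eye(n1) + b * np.ones((n1, n1)) / n1

def bias_curve(betas, rhos, n1: int = 10, sigma: float = 1.0) -> pd.DataFrame:
    """First component of the posterior-mean bias over a (beta, rho) grid,
    with the equicorrelated ``K11 = 0.5 I + 0.5 11'/n1`` and unit sigma
    used in the illustrative setting."""
    K11 = intraclass_cov(n1)
    rows = []
    for rho in np.atleast_1d(rhos):
        scale = ErrorScale(sigma2=sigma ** 2, rho=float(rho))
        for beta in np.atleast_1d(betas):
            val = selection_bias_from_beta(np.full(n1, float(beta)), K11, scale)[0]
            rows.append({"beta": float(beta), "rho": float(rho), "bias": float(val)})
    return pd.DataFrame(rows)


def marginal_effect_curve(alphas, rhos, gamma_k: float = 1.0, sigma: float = 1.0,
                          spec: MixingSpec | None = None) -> pd.DataFrame:
    rows = []
    for rho in np.atleast_1d(rhos):
        scale = ErrorScale(sigma2=sigma ** 2, rho=float(rho))
        for alpha in np.atleast_1d(alphas):
            val = marginal_effect_diff(gamma_k, scale, float(alpha), spec)
            rows.append({"alpha": float(alpha), "rho": float(rho), "diff": float(val)})
    return pd.DataFrame(rows)
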