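"""Scale-mixture-of-normals (SMN) machinery for the selection model.

An SMN error pair ``(eps, e)`` is bivariate normal with covariance
``delta(omega) * Sigma`` conditionally on a mixing draw ``omega ~ G``, where
``Sigma = [[sigma^2, rho*sigma], [rho*sigma, 1]]``.  The outcome ``y`` is
observed only when the latent selection score exceeds a threshold, i.e. the
selection error lies in the half-line ``C = (alpha, inf)`` with
``alpha = -v'gamma``.  This module provides:

* mixing-law specifications (:class:`MixingSpec`): the degenerate law
  (normal errors), gamma mixing with ``delta = 1/omega`` (Student-t errors),
  and a generic custom hook;
* the selection probability ``Fbar`` and the probability mass of the
  selection indicator;
* the skew-SMN density of a selected observation (the law of ``y | s = 1``);
* the observed-data log-likelihood of the full selection model.

All tail computations run in log space so the likelihood stays finite for
selection thresholds out to around +-8.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, logsumexp, roots_legendre

__all__ = [
    "MixingSpec",
    "SelectionInterval",
    "ErrorScale",
    "fbar",
    "log_fbar",
    "log_fbar_complement",
    "selection_pmf",
    "skew_smn_logpdf",
    "observed_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionInterval:
    """The half-line ``C = (alpha, inf)`` with ``alpha = -v'gamma``."""

    alpha: float

    @classmethod
    def from_gamma(cls, v: np.ndarray, gamma: np.ndarray) -> "SelectionInterval":
        return cls(alpha=-float(np.dot(np.asarray(v, float), np.asarray(gamma, float))))


@dataclass(frozen=True)
class ErrorScale:
    """Outcome error variance and selection correlation.

    The sampler works internally with the conjugate parametrization
    ``zeta = rho * sigma`` and ``tau2 = sigma^2 (1 - rho^2)``; the inverse
    map keeps ``|rho| < 1`` automatically.
    """

    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0.0):
            raise ValueError("sigma2 must be positive")
        if not (abs(self.rho) < 1.0):
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    @property
    def zeta(self) -> float:
        return self.rho * self.sigma

    @property
    def tau2(self) -> float:
        return self.sigma2 * (1.0 - self.rho ** 2)

    @property
    def Sigma(self) -> np.ndarray:
        rs = self.rho * self.sigma
        return np.array([[self.sigma2, rs], [rs, 1.0]])

    @classmethod
    def from_zeta_tau(cls, zeta: float, tau2: float) -> "ErrorScale":
        sigma2 = zeta ** 2 + tau2
        return cls(sigma2=sigma2, rho=zeta / np.sqrt(sigma2))


@dataclass(frozen=True)
class MixingSpec:
    """Mixing law ``G`` and scale function ``delta(omega)`` of an SMN family.

    ``kind`` is one of ``degenerate`` (delta == 1: normal errors),
    ``gamma_t`` (``omega ~ Gamma(nu/2, rate=nu/2)``, ``delta = 1/omega``:
    Student-t errors with ``nu`` degrees of freedom), or ``custom``.
    Custom laws supply ``delta``, a log-density ``log_g``, a sampler
    ``rvs(size, rng)`` and, when available, a quantile function ``ppf`` used
    for fixed-order Gauss-Legendre quadrature of the mixing integrals; a
    Monte-Carlo fallback is used otherwise.
    """

    kind: str
    nu: Optional[float] = None
    delta: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None, repr=False)
    log_g: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None, repr=False)
    ppf: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None, repr=False)
    rvs: Optional[Callable[..., np.ndarray]] = field(default=None, repr=False)
    n_nodes: int = 64
    n_mc: int = 20000

    # -- constructors ----------------------------------------------------

    @classmethod
    def degenerate(cls) -> "MixingSpec":
        return cls(kind="degenerate")

    @classmethod
    def gamma_t(cls, nu: float, n_nodes: int = 64) -> "MixingSpec":
        if not (nu > 0):
            raise ValueError("degrees of freedom nu must be positive")
        return cls(kind="gamma_t", nu=float(nu), n_nodes=n_nodes)

    @classmethod
    def custom(cls, delta, rvs, log_g=None, ppf=None, n_nodes: int = 64,
               n_mc: int = 20000) -> "MixingSpec":
        return cls(kind="custom", delta=delta, log_g=log_g, ppf=ppf, rvs=rvs,
                   n_nodes=n_nodes, n_mc=n_mc)

    # -- behaviour -------------------------------------------------------

    @property
    def is_degenerate(self) -> bool:
        return self.kind == "degenerate"

    def delta_of(self, omega: np.ndarray) -> np.ndarray:
        """The positive scale ``delta(omega)``."""
        omega = np.asarray(omega, dtype=float)
        if self.kind == "degenerate":
            return np.ones_like(omega)
        if self.kind == "gamma_t":
            return 1.0 / omega
        d = np.asarray(self.delta(omega), dtype=float)
        if (d <= 0).any():
            raise ValueError("delta(omega) must be positive")
        return d

    def draw_omega(self, size, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "degenerate":
            return np.ones(size)
        if self.kind == "gamma_t":
            return rng.gamma(self.nu / 2.0, 2.0 / self.nu, size=size)
        return np.asarray(self.rvs(size, rng), dtype=float)

    @functools.cached_property
    def _quad(self):
        """(delta nodes, log-weights) for the mixing integral.

        Gauss-Legendre nodes on the probability scale are mapped through the
        quantile function of G, giving equal-weight-style quadrature that is
        exact for the degenerate law and accurate for smooth mixing laws.
        Falls back to a deterministic Monte-Carlo node set when no quantile
        function is available.
        """
        if self.kind == "degenerate":
            return np.ones(1), np.zeros(1)
        x, w = roots_legendre(self.n_nodes)
        u = 0.5 * (x + 1.0)
        logw = np.log(0.5 * w)
        if self.kind == "gamma_t":
            omega = stats.gamma.ppf(u, a=self.nu / 2.0, scale=2.0 / self.nu)
        elif self.ppf is not None:
            omega = np.asarray(self.ppf(u), dtype=float)
        else:
            rng = np.random.default_rng(1234567)
            omega = np.asarray(self.rvs(self.n_mc, rng), dtype=float)
            logw = np.full(self.n_mc, -np.log(self.n_mc))
        return self.delta_of(omega), logw


# ---------------------------------------------------------------------------
# selection probability
# ---------------------------------------------------------------------------

def log_fbar(alpha, spec: MixingSpec, d: float = 0.0, tau: float = 1.0):
    """``log Fbar(C; d, tau)``, the log selection probability.

    ``Fbar`` integrates the normal upper-tail probability of ``(alpha, inf)``
    under ``N(d, delta(omega) * tau)`` over the mixing law.  For gamma
    mixing with ``delta = 1/omega`` the integral is a Student-t tail and is
    evaluated in closed form.
    """
    if not (tau > 0.0):
        raise ValueError("tau must be positive")
    alpha = np.asarray(alpha, dtype=float)
    std = (alpha - d) / np.sqrt(tau)
    if spec.kind == "degenerate":
        return log_ndtr(-std)
    if spec.kind == "gamma_t":
        return stats.t.logsf(std, df=spec.nu)
    delta, logw = spec._quad
    terms = logw[:, None] + log_ndtr(-std[None, ...] / np.sqrt(delta)[:, None])
    return logsumexp(terms, axis=0)


def log_fbar_complement(alpha, spec: MixingSpec, d: float = 0.0, tau: float = 1.0):
    """``log (1 - Fbar)``, the log non-selection probability."""
    if not (tau > 0.0):
        raise ValueError("tau must be positive")
    alpha = np.asarray(alpha, dtype=float)
    std = (alpha - d) / np.sqrt(tau)
    if spec.kind == "degenerate":
        return log_ndtr(std)
    if spec.kind == "gamma_t":
        return stats.t.logcdf(std, df=spec.nu)
    delta, logw = spec._quad
    terms = logw[:, None] + log_ndtr(std[None, ...] / np.sqrt(delta)[:, None])
    return logsumexp(terms, axis=0)


def fbar(C: SelectionInterval | float, d: float = 0.0, tau: float = 1.0,
         spec: MixingSpec = None):
    """Selection probability ``Fbar(C; d, tau)`` in ``[0, 1]``."""
    spec = MixingSpec.degenerate() if spec is None else spec
    alpha = C.alpha if isinstance(C, SelectionInterval) else C
    return np.exp(log_fbar(alpha, spec, d=d, tau=tau))


def selection_pmf(s, C: SelectionInterval | float, spec: MixingSpec = None):
    """Probability mass of the selection indicator, ``Fbar^s (1-Fbar)^(1-s)``."""
    spec = MixingSpec.degenerate() if spec is None else spec
    alpha = C.alpha if isinstance(C, SelectionInterval) else C
    s = np.asarray(s)
    if not np.isin(s, (0, 1)).all():
        raise ValueError("s must be 0 or 1")
    lf = log_fbar(alpha, spec)
    lc = log_fbar_complement(alpha, spec)
    return np.exp(np.where(s == 1, lf, lc))


# ---------------------------------------------------------------------------
# skew-SMN density of a selected observation
# ---------------------------------------------------------------------------

def skew_smn_logpdf(y, eta_i, scale: ErrorScale, C: SelectionInterval | float,
                    spec: MixingSpec = None):
    """Log-density of ``y | s = 1`` (the skew-SMN selection distribution).

    Conditionally on the mixing draw, ``y`` is normal with variance
    ``delta * sigma^2`` and the selection error given ``y`` is normal with
    mean ``theta = rho (y - eta) / sigma`` and variance
    ``delta * (1 - rho^2)``; the density is the mixing average of the
    normal density times the conditional selection probability, normalized
    by the marginal selection probability ``Fbar(C; 0, 1)``.
    """
    spec = MixingSpec.degenerate() if spec is None else spec
    alpha = C.alpha if isinstance(C, SelectionInterval) else C
    y = np.asarray(y, dtype=float)
    eta_i = np.asarray(eta_i, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    sigma2, rho = scale.sigma2, scale.rho
    sigma = scale.sigma
    r = y - eta_i
    theta = rho * r / sigma
    s2_cond = 1.0 - rho ** 2
    log_norm = log_fbar(alpha, spec)
    if spec.is_degenerate:
        lp = (-0.5 * (_LOG_2PI + np.log(sigma2)) - 0.5 * r * r / sigma2
              + log_ndtr((theta - alpha) / np.sqrt(s2_cond)))
        return lp - log_norm
    delta, logw = spec._quad
    out_shape = np.broadcast_shapes(r.shape, alpha.shape)
    rr = np.broadcast_to(r, out_shape).reshape(-1)
    th = np.broadcast_to(theta, out_shape).reshape(-1)
    al = np.broadcast_to(alpha, out_shape).reshape(-1)
    dd = delta[:, None]
    terms = (logw[:, None]
             - 0.5 * (_LOG_2PI + np.log(dd * sigma2))
             - 0.5 * (rr * rr)[None, :] / (dd * sigma2)
             + log_ndtr((th[None, :] - al[None, :]) / np.sqrt(dd * s2_cond)))
    return (logsumexp(terms, axis=0) - np.broadcast_to(log_norm, out_shape)
            .reshape(-1)).reshape(out_shape)


# ---------------------------------------------------------------------------
# observed-data log-likelihood
# ---------------------------------------------------------------------------

def observed_loglik(eta1, scale: ErrorScale, gamma, data, spec: MixingSpec = None) -> float:
    """Observed-data log-likelihood of the selection GP model.

    Sums, over all records, the Bernoulli selection term and -- for the
    selected records -- the skew-SMN log-density of the observed outcome,
    with the latent selection scores and mixing scales integrated out.
    ``data`` must be in selected-first order.
    """
    spec = MixingSpec.degenerate() if spec is None else spec
    eta1 = np.asarray(eta1, dtype=float).reshape(-1)
    gamma = np.asarray(gamma, dtype=float).reshape(-1)
    n1 = data.n1
    if eta1.shape[0] != n1:
        raise ValueError("eta1 must have one entry per selected record")
    if np.isnan(data.y[:n1]).any():
        raise ValueError("selected records with missing outcomes")
    if data.n == 0:
        return 0.0
    alphas = -(data.V @ gamma)
    ll = float(np.sum(log_fbar(alphas[:n1], spec)))
    ll += float(np.sum(log_fbar_complement(alphas[n1:], spec)))
    if n1 > 0:
        ll += float(np.sum(skew_smn_logpdf(data.y1, eta1, scale, alphas[:n1], spec)))
    return ll
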