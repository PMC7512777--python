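"""Covariance kernels, the maximum-entropy (Gaussian-process) prior, and the
closed-form GP-regression posterior.

The maximum-entropy prior for a regression function constrained only in its
mean and covariance functions is Gaussian, so the nonparametric prior used
throughout the package is a Gaussian process ``GP(m, K)``.  With i.i.d.
normal noise of variance ``sigma2`` the posterior of the function values at
the observed inputs is available in closed form (:func:`gpr_posterior`); it
serves both as the no-selection baseline and as an oracle for the Gibbs
sampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "MeanSpec",
    "kernel_matrix",
    "kernel_cross",
    "maxent_log_prior",
    "gpr_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class KernelSpec:
    """Covariance-function specification.

    Parameters
    ----------
    u0 : float
        Global scale (the prior marginal variance of the regression
        function).  Must be positive.
    w0 : float
        Smoothing rate of the squared-exponential kernel; the prior
        correlation length is ``1/sqrt(w0)``.  Must be positive.
    jitter : float, optional
        Nonnegative ridge added to the diagonal before factorization.
        Defaults to ``1e-8 * u0``; dense one-dimensional designs make
        squared-exponential Gram matrices numerically singular without it.
    func : callable, optional
        User-supplied covariance ``func(X, Z) -> |X| x |Z| matrix``.  When
        given, ``form`` must be ``"user_supplied"`` and ``u0``/``w0`` are
        ignored by the evaluation (but still validated).
    """

    u0: float
    w0: float
    jitter: Optional[float] = None
    form: str = "squared_exponential"
    func: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if not (self.u0 > 0.0):
            raise ValueError("kernel scale u0 must be positive")
        if not (self.w0 > 0.0):
            raise ValueError("kernel smoothing rate w0 must be positive")
        if self.form not in ("squared_exponential", "user_supplied"):
            raise ValueError(f"unknown kernel form {self.form!r}")
        if self.form == "user_supplied" and self.func is None:
            raise ValueError("user_supplied kernel requires func")
        if self.jitter is not None and self.jitter < 0.0:
            raise ValueError("jitter must be nonnegative")

    @property
    def effective_jitter(self) -> float:
        return 1e-8 * self.u0 if self.jitter is None else self.jitter


@dataclass(frozen=True)
class MeanSpec:
    """Prior mean function; the default is identically zero."""

    func: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.func is None:
            return np.zeros(X.shape[0])
        m = np.asarray(self.func(X), dtype=float).reshape(-1)
        if m.shape[0] != X.shape[0]:
            raise ValueError("mean function returned wrong length")
        return m


def _as_design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite entries")
    return X


def kernel_cross(X, Z, spec: KernelSpec) -> np.ndarray:
    """Cross-covariance matrix between two designs (no jitter)."""
    X, Z = _as_design(X), _as_design(Z)
    if spec.form == "user_supplied":
        return np.asarray(spec.func(X, Z), dtype=float)
    sq = cdist(X, Z, metric="sqeuclidean")
    return spec.u0 * np.exp(-0.5 * spec.w0 * sq)


def kernel_matrix(X, spec: KernelSpec) -> np.ndarray:
    """Gram matrix of the design under ``spec``, with diagonal jitter.

    Entry ``(i, j)`` equals ``u0 * exp(-(w0/2) * ||x_i - x_j||^2)`` for the
    squared-exponential form; the output is symmetric with diagonal
    ``u0 + jitter``.
    """
    K = kernel_cross(X, X, spec)
    K = 0.5 * (K + K.T)
    n = K.shape[0]
    K[np.diag_indices(n)] += spec.effective_jitter
    return K


def maxent_log_prior(eta, m, K) -> float:
    """Log-density of the maximum-entropy (multivariate normal) prior.

    Raises
    ------
    ValueError
        If ``K`` is not symmetric positive definite (the differential
        entropy, and hence the prior, is undefined).
    """
    eta = np.asarray(eta, dtype=float).reshape(-1)
    m = np.asarray(m, dtype=float).reshape(-1)
    K = np.asarray(K, dtype=float)
    n = eta.shape[0]
    if m.shape[0] != n or K.shape != (n, n):
        raise ValueError("dimension mismatch between eta, m and K")
    try:
        c, low = cho_factor(K, lower=True)
    except LinAlgError as err:
        raise ValueError("covariance matrix is not positive definite") from err
    diff = eta - m
    quad = float(diff @ cho_solve((c, low), diff))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return -0.5 * (n * _LOG_2PI + logdet + quad)


def gpr_posterior(y, m, K, sigma2: float):
    """Closed-form GP-regression posterior of the function values.

    Returns the mean ``K(K+sigma2 I)^{-1} y + sigma2 (K+sigma2 I)^{-1} m``
    and covariance ``sigma2 K (K+sigma2 I)^{-1}``.  All solves go through a
    Cholesky factorization of ``K + sigma2 I``.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    m = np.asarray(m, dtype=float).reshape(-1)
    K = np.asarray(K, dtype=float)
    n = y.shape[0]
    if m.shape[0] != n or K.shape != (n, n):
        raise ValueError("dimension mismatch between y, m and K")
    if sigma2 < 0.0:
        raise ValueError("sigma2 must be nonnegative")
    A = K + sigma2 * np.eye(n)
    c, low = cho_factor(A, lower=True)
    mean = K @ cho_solve((c, low), y) + sigma2 * cho_solve((c, low), m)
    cov = sigma2 * (K @ cho_solve((c, low), np.eye(n)))
    cov = 0.5 * (cov + cov.T)
    return mean, cov
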