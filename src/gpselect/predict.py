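"""Bias-corrected prediction of the regression function and outcomes at
unselected or new inputs.

Conditioning the joint GP prior over training and test function values on a
training draw gives the usual Gaussian predictive law; feeding each retained
posterior draw of ``eta_n1`` through it yields draws of ``eta_n2`` whose
Monte-Carlo average is the bias-corrected point prediction, since the
training draws come from the selection-aware posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from .gp_core import KernelSpec, MeanSpec, kernel_cross, kernel_matrix
from .smn import MixingSpec

__all__ = ["KernelBlocks", "conditional_eta2", "predictive_y2", "summarize_prediction"]


@dataclass
class KernelBlocks:
    """Precomputed train/test covariance blocks and conditioning operators."""

    K11: np.ndarray
    K12: np.ndarray
    K22: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    A: np.ndarray = None        # K21 K11^{-1}
    L_schur: np.ndarray = None  # lower Cholesky of K22 - K21 K11^{-1} K12

    @classmethod
    def from_kernel(cls, X1, X2, kernel: KernelSpec, mean: MeanSpec | None = None,
                    jitter: Optional[float] = None) -> "KernelBlocks":
        mean = MeanSpec() if mean is None else mean
        K11 = kernel_matrix(X1, kernel)
        K12 = kernel_cross(X1, X2, kernel)
        K22 = kernel_matrix(X2, kernel)
        return cls.from_blocks(K11, K12, K22, mean(X1), mean(X2),
                               jitter=kernel.effective_jitter if jitter is None else jitter)

    @classmethod
    def from_blocks(cls, K11, K12, K22, m1, m2, jitter: float = 0.0) -> "KernelBlocks":
        K11 = np.asarray(K11, float)
        K12 = np.asarray(K12, float)
        K22 = np.asarray(K22, float)
        c = cho_factor(K11, lower=True)
        A = cho_solve(c, K12).T          # K21 K11^{-1}
        S = K22 - A @ K12
        S = 0.5 * (S + S.T)
        S[np.diag_indices_from(S)] += max(jitter, 0.0)
        try:
            L = cholesky(S, lower=True)
        except np.linalg.LinAlgError:
            # clip tiny negative eigenvalues to zero
            vals, vecs = np.linalg.eigh(S)
            S = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
            S[np.diag_indices_from(S)] += 1e-12 * max(1.0, np.max(np.diag(K22)))
            L = cholesky(S, lower=True)
        return cls(K11=K11, K12=K12, K22=K22, m1=np.asarray(m1, float),
                   m2=np.asarray(m2, float), A=A, L_schur=L)

    def conditional_mean(self, eta1: np.ndarray) -> np.ndarray:
        return self.m2 + self.A @ (np.asarray(eta1, float) - self.m1)

    def conditional_draw(self, eta1: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mean = self.conditional_mean(eta1)
        return mean + self.L_schur @ rng.standard_normal(mean.shape[0])


def conditional_eta2(eta1_draw, blocks: KernelBlocks, rng: np.random.Generator):
    """One draw of the test-point regression function given a training draw."""
    return blocks.conditional_draw(eta1_draw, rng)


def predictive_y2(eta2_draw, sigma2: float, spec: MixingSpec | None,
                  rng: np.random.Generator) -> np.ndarray:
    """Outcome draw at test points: adds SMN noise with fresh mixing draws.

    Test-point mixing scales are not identified by the data, so they are
    sampled from the prior mixing law.
    """
    spec = MixingSpec.degenerate() if spec is None else spec
    eta2 = np.asarray(eta2_draw, float)
    omega = spec.draw_omega(eta2.shape[0], rng)
    delta = spec.delta_of(omega)
    return eta2 + np.sqrt(sigma2 * delta) * rng.standard_normal(eta2.shape[0])


def summarize_prediction(draws: np.ndarray, x: Optional[np.ndarray] = None,
                         level: float = 0.95) -> pd.DataFrame:
    """Pointwise posterior mean and equal-tail percentile band.

    Percentiles use linear interpolation between order statistics (the
    numpy default), which matters for band widths at small chain lengths.
    """
    draws = np.atleast_2d(np.asarray(draws, float))
    lo = 100.0 * (1.0 - level) / 2.0
    hi = 100.0 - lo
    qs = np.percentile(draws, [lo, hi], axis=0, method="linear")
    out = pd.DataFrame({
        "posterior_mean": draws.mean(axis=0),
        "lo95": qs[0],
        "hi95": qs[1],
    })
    if x is not None:
        x = np.asarray(x, float)
        out.insert(0, "x", x[:, 0] if x.ndim == 2 else x)
    return out
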