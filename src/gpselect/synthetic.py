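"""Synthetic sample-selection data generators.

The simulation designs share the outcome function ``f(x) = 50x + 5 sin(10x)``
on ``x in (0, 1)``, an intercept-only probit-type selection equation
``z = gamma + e`` with ``s = 1{z >= 0}``, and correlated error pairs
``(eps, e)`` with ``rho = 0.5`` and ``sigma = 3``:

* Model 1 -- bivariate normal errors;
* Model 2 -- bivariate Student-t10-type errors (one shared
  ``omega ~ Gamma(5, 5)`` per record scaling both components by
  ``1/sqrt(omega)``);
* Model 3 -- a five-component bivariate normal mixture with weights
  (0.4, 0.2, 0.2, 0.1, 0.1) over outcome variances ``9k``,
  ``k in (1, 2, 4, 8, 16)`` (selection variance stays 1).

Defaults are ``n = 300`` with an expected half of the outcomes selected
(``gamma = 0``); ``exact_n1`` regenerates whole datasets until the selected
count hits the target, which preserves the model law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import SelectionDataset
from .smn import ErrorScale, MixingSpec

__all__ = ["SimDesign", "true_function", "draw_errors", "generate",
           "DEFAULT_MIXTURE"]

#: (weight, outcome-variance scale factor k) rows of the Model-3 mixture.
DEFAULT_MIXTURE = ((0.4, 1.0), (0.2, 2.0), (0.2, 4.0), (0.1, 8.0), (0.1, 16.0))


@dataclass
class SimDesign:
    """One simulation design."""

    n: int = 300
    target_n1: int = 150
    model_id: int | str = 1
    gamma: float = 0.0
    rho: float = 0.5
    sigma: float = 3.0
    nu: float = 10.0
    mixture: tuple = DEFAULT_MIXTURE
    seed: Optional[int] = None
    exact_n1: bool = False
    x_mode: str = "uniform"
    retry_limit: int = 10000

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, "custom"):
            raise ValueError("model_id must be 1, 2, 3 or 'custom'")
        if self.x_mode not in ("uniform", "grid"):
            raise ValueError("x_mode must be 'uniform' or 'grid'")
        if self.model_id == 3:
            w = sum(p for p, _ in self.mixture)
            if abs(w - 1.0) > 1e-12:
                raise ValueError("mixture weights must sum to 1")

    @property
    def scale(self) -> ErrorScale:
        return ErrorScale(sigma2=self.sigma ** 2, rho=self.rho)


def true_function(x):
    """The simulated regression function ``50x + 5 sin(10x)``."""
    x = np.asarray(x, dtype=float)
    return 50.0 * x + 5.0 * np.sin(10.0 * x)


def draw_errors(n: int, scale: ErrorScale, model, rng: np.random.Generator,
                nu: float = 10.0, mixture=DEFAULT_MIXTURE) -> np.ndarray:
    """n x 2 matrix of (outcome, selection) error pairs.

    ``model`` selects the error law: 1 bivariate normal, 2 shared-scale
    Student-t type (``delta = 1/omega``, ``omega ~ Gamma(nu/2, nu/2)``),
    3 bivariate normal mixture.  A :class:`MixingSpec` may be passed instead
    to draw from an arbitrary SMN law.
    """
    L = np.linalg.cholesky(scale.Sigma)
    zz = rng.standard_normal((n, 2)) @ L.T
    if isinstance(model, MixingSpec):
        delta = model.delta_of(model.draw_omega(n, rng))
        return zz * np.sqrt(delta)[:, None]
    if model == 1:
        return zz
    if model == 2:
        omega = rng.gamma(nu / 2.0, 2.0 / nu, size=n)
        return zz / np.sqrt(omega)[:, None]
    if model == 3:
        weights = np.array([p for p, _ in mixture])
        ks = np.array([k for _, k in mixture])
        comp = rng.choice(len(ks), size=n, p=weights)
        # Sigma(k): outcome variance sigma2*k, selection variance 1,
        # covariance rho*sigma*sqrt(k)
        out = np.empty((n, 2))
        s2k = scale.sigma2 * ks[comp]
        cov = scale.rho * scale.sigma * np.sqrt(ks[comp])
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        out[:, 0] = np.sqrt(s2k) * e1
        c_on_s = cov / np.sqrt(s2k)          # regression of e on eps
        resid_sd = np.sqrt(1.0 - cov ** 2 / s2k)
        out[:, 1] = c_on_s * e1 + resid_sd * e2
        return out
    raise ValueError(f"unknown error model {model!r}")


def generate(design: SimDesign, rng: Optional[np.random.Generator] = None) -> SelectionDataset:
    """Generate one selection dataset; selected-first ordered, reproducible."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    for _ in range(design.retry_limit if design.exact_n1 else 1):
        if design.x_mode == "grid":
            x = (np.arange(design.n) + 0.5) / design.n
        else:
            x = rng.random(design.n)
        err = draw_errors(design.n, design.scale, design.model_id, rng,
                          nu=design.nu, mixture=design.mixture)
        z = design.gamma + err[:, 1]
        s = (z >= 0).astype(int)
        if design.exact_n1 and int(s.sum()) != design.target_n1:
            continue
        y = true_function(x) + err[:, 0]
        y = np.where(s == 1, y, np.nan)
        v = np.ones((design.n, 1))
        return SelectionDataset.from_arrays(X=x[:, None], V=v, s=s, y=y)
    raise RuntimeError(
        f"exact_n1={design.target_n1} not reached in {design.retry_limit} tries")
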