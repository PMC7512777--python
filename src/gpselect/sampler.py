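"""Gibbs/Metropolis sampler for the selection GP regression model.

The hierarchy (conjugate parametrization ``zeta = rho*sigma``,
``tau2 = sigma^2(1 - rho^2)``):

    y_i | omega_i, z_i, s_i=1  ~  N(eta(x_i) + zeta*z_Ci, delta(omega_i) tau2)
    s_i = 1{z_i >= 0},   z_i | omega_i ~ N(v_i'gamma, delta(omega_i))
    omega_i ~ G,         eta_n1 ~ N(m1, K11)
    zeta | tau2 ~ N(theta0, sigma0 tau2),  tau2 ~ IG(c, d),  gamma ~ N(gamma0, Omega0)

Every full conditional is standard (normal, inverse-gamma, truncated normal,
gamma for Student-t mixing); a Metropolis step is used only for custom
mixing laws and for the kernel smoothing rate when kernel hyperparameters
are sampled.  The `gpr_baseline` mode pins ``zeta = 0`` and drops the
selection equation, i.e. it fits an ordinary (robust) GP regression to the
selected records only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import ndtri

from .data import SelectionDataset
from .gp_core import KernelSpec, MeanSpec, kernel_cross, kernel_matrix
from .smn import MixingSpec
from .truncnorm import sample_lower_truncated, sample_upper_truncated

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "ModelState",
    "PosteriorChains",
    "run_gibbs",
    "cond_eta",
    "cond_tau2",
    "cond_zeta",
    "cond_z",
    "cond_gamma",
    "cond_omega",
    "cond_kernel_hyper",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Hyperparameters of the Bayesian hierarchy.

    Defaults mirror the diffuse choices used throughout the simulation
    studies: ``theta0=0, sigma0=10, c=d=0.001, gamma0=0, Omega0=10*I``.
    ``a, b`` (inverse-gamma for the kernel scale u0) and ``c_w, d_w``
    (half-Cauchy for the smoothing rate w0) only matter when
    ``sample_kernel_hyper`` is switched on; by default the kernel
    hyperparameters stay fixed at their user-supplied values.
    """

    theta0: float = 0.0
    sigma0: float = 10.0
    c: float = 0.001
    d: float = 0.001
    gamma0: Optional[np.ndarray] = None
    Omega0: float | np.ndarray = 10.0
    a: float = 2.0
    b: float = 1.0
    c_w: float = 0.0
    d_w: float = 5.0
    sample_kernel_hyper: bool = False

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.c <= 0 or self.d <= 0:
            raise ValueError("sigma0, c, d must be positive")
        if self.b <= 0 or self.d_w <= 0:
            raise ValueError("b and d_w must be positive")

    def gamma_mean(self, q: int) -> np.ndarray:
        if self.gamma0 is None:
            return np.zeros(q)
        g0 = np.asarray(self.gamma0, dtype=float).reshape(-1)
        if g0.shape[0] != q:
            raise ValueError("gamma0 has wrong length")
        return g0

    def omega0_matrix(self, q: int) -> np.ndarray:
        O = np.asarray(self.Omega0, dtype=float)
        if O.ndim == 0:
            return float(O) * np.eye(q)
        if O.shape != (q, q):
            raise ValueError("Omega0 has wrong shape")
        return O


@dataclass
class ChainConfig:
    """MCMC run plan: 5000 burn-in, 15000 raw draws thinned by 5 -> 3000
    retained, matching the simulation sampling plan."""

    n_burn: int = 5000
    n_keep_raw: int = 15000
    thin: int = 5
    seed: int = 0
    w0_step: float = 0.4
    omega_step: float = 0.6
    adapt: bool = True
    fix_tau2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_keep_raw % self.thin != 0:
            raise ValueError("n_keep_raw must be a multiple of thin")

    @property
    def n_retained(self) -> int:
        return self.n_keep_raw // self.thin


@dataclass
class ModelState:
    """One Gibbs state."""

    eta1: np.ndarray
    zeta: float
    tau2: float
    gamma: np.ndarray
    z: np.ndarray
    omega: np.ndarray
    u0: float
    w0: float

    @property
    def sigma2(self) -> float:
        return self.zeta ** 2 + self.tau2

    @property
    def rho(self) -> float:
        return self.zeta / np.sqrt(self.sigma2)


@dataclass
class PosteriorChains:
    """Retained, thinned posterior draws plus run provenance."""

    eta1: np.ndarray          # (R, n1)
    zeta: np.ndarray          # (R,)
    tau2: np.ndarray          # (R,)
    gamma: np.ndarray         # (R, q)
    u0: np.ndarray            # (R,)
    w0: np.ndarray            # (R,)
    eta2: Optional[np.ndarray] = None   # (R, n2)
    y2: Optional[np.ndarray] = None     # (R, n2)
    X1: Optional[np.ndarray] = None
    X2: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def sigma2(self) -> np.ndarray:
        return self.zeta ** 2 + self.tau2

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.sigma2)

    @property
    def rho(self) -> np.ndarray:
        return self.zeta / np.sqrt(self.sigma2)

    @property
    def n_retained(self) -> int:
        return self.zeta.shape[0]

    def save(self, outdir) -> None:
        """One CSV per parameter block plus a JSON run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.eta1).to_csv(outdir / "eta1.csv", index=False)
        pd.DataFrame(self.gamma, columns=[f"gamma{j+1}" for j in range(self.gamma.shape[1])]
                     ).to_csv(outdir / "gamma.csv", index=False)
        scalars = pd.DataFrame({
            "zeta": self.zeta, "tau2": self.tau2,
            "sigma2": self.sigma2, "rho": self.rho,
            "u0": self.u0, "w0": self.w0,
        })
        scalars.to_csv(outdir / "scalars.csv", index=False)
        for name, arr in (("eta2", self.eta2), ("y2", self.y2)):
            if arr is not None:
                pd.DataFrame(arr).to_csv(outdir / f"{name}.csv", index=False)
        for name, arr in (("X1", self.X1), ("X2", self.X2)):
            if arr is not None:
                pd.DataFrame(arr).to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=_json_default)

    @classmethod
    def load(cls, outdir) -> "PosteriorChains":
        outdir = Path(outdir)
        scalars = pd.read_csv(outdir / "scalars.csv")

        def _opt(name):
            p = outdir / f"{name}.csv"
            return pd.read_csv(p).to_numpy() if p.exists() else None

        with open(outdir / "manifest.json") as fh:
            meta = json.load(fh)
        return cls(
            eta1=pd.read_csv(outdir / "eta1.csv").to_numpy(),
            zeta=scalars["zeta"].to_numpy(),
            tau2=scalars["tau2"].to_numpy(),
            gamma=pd.read_csv(outdir / "gamma.csv").to_numpy(),
            u0=scalars["u0"].to_numpy(),
            w0=scalars["w0"].to_numpy(),
            eta2=_opt("eta2"), y2=_opt("y2"), X1=_opt("X1"), X2=_opt("X2"),
            meta=meta,
        )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


# ---------------------------------------------------------------------------
# full conditional posteriors
# ---------------------------------------------------------------------------

def eta_params(K11_inv, m1, y1, zeta, z_C1, tau2, delta1):
    """Mean and upper-Cholesky factor of the precision of eta_n1 | rest.

    Precision = K11^{-1} + D1^{-1}/tau2; mean solves
    precision * mean = K11^{-1} m1 + D1^{-1}(y - zeta z_C)/tau2.
    """
    w = 1.0 / (delta1 * tau2)
    prec = K11_inv + np.diag(w)
    U = cholesky(prec, lower=False, check_finite=False)
    rhs = K11_inv @ m1 + w * (y1 - zeta * z_C1)
    mean = cho_solve((U, False), rhs, check_finite=False)
    return mean, U


def cond_eta(state: ModelState, y1, K11_inv, m1, delta1, z_C1, rng) -> np.ndarray:
    """Draw the regression-function values at the selected inputs."""
    n1 = y1.shape[0]
    if n1 == 0:
        return np.empty(0)
    mean, U = eta_params(K11_inv, m1, y1, state.zeta, z_C1, state.tau2, delta1)
    return mean + solve_triangular(U, rng.standard_normal(n1), lower=False,
                                   check_finite=False)


def tau2_params(priors: PriorSpec, resid, delta1, zeta, include_zeta: bool = True):
    """Shape and scale of the inverse-gamma conditional of tau2."""
    n1 = resid.shape[0]
    shape = priors.c + (n1 + (1 if include_zeta else 0)) / 2.0
    scale = priors.d + 0.5 * float(np.sum(resid * resid / delta1))
    if include_zeta:
        scale += (zeta - priors.theta0) ** 2 / (2.0 * priors.sigma0)
    return shape, scale


def cond_tau2(state: ModelState, y1, eta1, z_C1, delta1, priors: PriorSpec, rng,
              include_zeta: bool = True) -> float:
    resid = y1 - eta1 - state.zeta * z_C1
    shape, scale = tau2_params(priors, resid, delta1, state.zeta, include_zeta)
    return scale / rng.gamma(shape)


def zeta_params(priors: PriorSpec, y1, eta1, z_C1, delta1, tau2):
    """Mean and variance of the normal conditional of zeta."""
    r = y1 - eta1
    denom = 1.0 / priors.sigma0 + float(np.sum(z_C1 * z_C1 / delta1))
    mean = (priors.theta0 / priors.sigma0 + float(np.sum(r * z_C1 / delta1))) / denom
    var = tau2 / denom
    return mean, var


def cond_zeta(state: ModelState, y1, eta1, z_C1, delta1, priors: PriorSpec, rng) -> float:
    mean, var = zeta_params(priors, y1, eta1, z_C1, delta1, state.tau2)
    return mean + np.sqrt(var) * rng.standard_normal()


def z_params(Vg, y, eta_full, zeta, tau2, delta, n1):
    """Location and scale of the truncated-normal conditionals of z.

    Selected records (first n1): TN_(0,inf)(v'gamma + zeta(y-eta)/(zeta^2+tau2),
    delta*tau2/(zeta^2+tau2)); unselected: TN_(-inf,0)(v'gamma, delta).
    """
    loc = Vg.copy()
    sd = np.sqrt(delta)
    if n1 > 0:
        s2 = zeta ** 2 + tau2
        loc[:n1] = Vg[:n1] + zeta * (y[:n1] - eta_full) / s2
        sd[:n1] = np.sqrt(delta[:n1] * tau2 / s2)
    return loc, sd


def cond_z(state: ModelState, data: SelectionDataset, delta, rng) -> np.ndarray:
    n1 = data.n1
    Vg = data.V @ state.gamma
    loc, sd = z_params(Vg, data.y, state.eta1, state.zeta, state.tau2, delta, n1)
    z = np.empty(data.n)
    if n1 > 0:
        z[:n1] = sample_lower_truncated(loc[:n1], sd[:n1], 0.0, rng)
    if n1 < data.n:
        z[n1:] = sample_upper_truncated(loc[n1:], sd[n1:], 0.0, rng)
    return z


def gamma_params(priors: PriorSpec, data: SelectionDataset, z, eta1, zeta, tau2, delta):
    """Mean and covariance of the normal conditional of gamma."""
    n1, q = data.n1, data.q
    O0inv = np.linalg.inv(priors.omega0_matrix(q))
    Vw = data.V / delta[:, None]
    A = O0inv + data.V.T @ Vw
    b = O0inv @ priors.gamma_mean(q) + Vw.T @ z
    if n1 > 0:
        V1w = data.V[:n1] / (tau2 * delta[:n1, None])
        A = A + zeta ** 2 * (data.V[:n1].T @ (data.V[:n1] / (tau2 * delta[:n1, None])))
        b = b + zeta * (V1w.T @ (zeta * z[:n1] + eta1 - data.y[:n1]))
    cov = np.linalg.inv(A)
    cov = 0.5 * (cov + cov.T)
    return cov @ b, cov


def cond_gamma(state: ModelState, data: SelectionDataset, delta, priors: PriorSpec,
               rng) -> np.ndarray:
    mean, cov = gamma_params(priors, data, state.z, state.eta1, state.zeta,
                             state.tau2, delta)
    L = cholesky(cov, lower=True, check_finite=False)
    return mean + L @ rng.standard_normal(mean.shape[0])


def omega_gamma_params(nu, z_C, resid, tau2, n1, include_selection: bool = True):
    """Shape/rate arrays of the conjugate gamma conditionals of omega
    under gamma mixing with delta = 1/omega.

    Selected records combine the outcome and selection-score residuals:
    Gamma((nu+2)/2, nu/2 + z_C^2/2 + (y-eta-zeta z_C)^2/(2 tau2)); unselected
    records use the score only: Gamma((nu+1)/2, nu/2 + z_C^2/2).  With the
    selection equation dropped (baseline mode), selected records use
    Gamma((nu+1)/2, nu/2 + resid^2/(2 tau2)).
    """
    n = z_C.shape[0] if include_selection else n1
    shape = np.full(n, (nu + 1.0) / 2.0)
    rate = np.full(n, nu / 2.0)
    if include_selection:
        rate += 0.5 * z_C * z_C
        shape[:n1] = (nu + 2.0) / 2.0
        rate[:n1] += 0.5 * resid * resid / tau2
    else:
        rate[:n1] += 0.5 * resid * resid / tau2
    return shape, rate


def cond_omega(state: ModelState, data: SelectionDataset, spec: MixingSpec, rng,
               include_selection: bool = True, mh_step: float = 0.6) -> np.ndarray:
    """Update the mixing scales; a no-op for the degenerate law."""
    if spec.is_degenerate:
        return state.omega
    n1 = data.n1
    if include_selection:
        z_C = state.z - data.V @ state.gamma
        resid = data.y[:n1] - state.eta1 - state.zeta * z_C[:n1]
    else:
        z_C = np.zeros(n1)
        resid = data.y[:n1] - state.eta1
    if spec.kind == "gamma_t":
        shape, rate = omega_gamma_params(spec.nu, z_C, resid, state.tau2, n1,
                                         include_selection)
        draw = rng.gamma(shape) / rate
        if include_selection:
            return draw
        out = state.omega.copy()
        out[:n1] = draw
        return out
    return _omega_mh(state, z_C, resid, spec, rng, n1, include_selection, mh_step)


def _omega_mh(state, z_C, resid, spec, rng, n1, include_selection, step):
    """One log-normal random-walk Metropolis step per record targeting the
    generic mixing conditional."""
    cur = state.omega.copy()
    n = cur.shape[0] if include_selection else n1
    prop = cur[:n] * np.exp(step * rng.standard_normal(n))

    def log_target(om):
        d = spec.delta_of(om)
        lt = np.asarray(spec.log_g(om), dtype=float).copy()
        if include_selection:
            lt += -0.5 * np.log(d) - 0.5 * z_C * z_C / d
            lt[:n1] += (-0.5 * np.log(d[:n1] * state.tau2)
                        - 0.5 * resid * resid / (d[:n1] * state.tau2))
        else:
            lt[:n1] += (-0.5 * np.log(d[:n1] * state.tau2)
                        - 0.5 * resid * resid / (d[:n1] * state.tau2))
        return lt

    # log-normal proposal: Jacobian term log(prop/cur)
    log_acc = log_target(prop) - log_target(cur[:n]) + np.log(prop / cur[:n])
    accept = np.log(rng.random(n)) <= log_acc
    out = state.omega.copy()
    out[:n][accept] = prop[accept]
    return out


def kernel_hyper_params(priors: PriorSpec, eta1, m1, R_inv):
    """Shape and scale of the inverse-gamma conditional of the kernel scale
    u0, given the correlation matrix R(w0) (K11 = u0 * R)."""
    n1 = eta1.shape[0]
    diff = eta1 - m1
    quad = float(diff @ (R_inv @ diff))
    return priors.a + n1 / 2.0, priors.b + 0.5 * quad


def _log_half_cauchy(w0, c_w, d_w):
    if w0 <= c_w:
        return -np.inf
    return -np.log(1.0 + ((w0 - c_w) / d_w) ** 2)


def cond_kernel_hyper(state: ModelState, X1, m1, priors: PriorSpec,
                      kernel: KernelSpec, rng, step: float = 0.4):
    """Draw (u0, w0): conjugate inverse-gamma for u0, one log-scale
    random-walk Metropolis step for w0 targeting the GP prior times its
    half-Cauchy hyperprior.  Returns (u0, w0, accepted)."""
    n1 = state.eta1.shape[0]
    spec_R = KernelSpec(u0=1.0, w0=state.w0, jitter=kernel.effective_jitter / max(state.u0, 1e-300))
    R = kernel_matrix(X1, spec_R) if n1 > 0 else np.empty((0, 0))
    if n1 > 0:
        cR = cho_factor(R, lower=True)
        R_inv = cho_solve(cR, np.eye(n1))
        shape, scale = kernel_hyper_params(priors, state.eta1, m1, R_inv)
    else:
        shape, scale = priors.a, priors.b
    u0_new = scale / rng.gamma(shape)

    def log_post_w0(w0):
        lp = _log_half_cauchy(w0, priors.c_w, priors.d_w)
        if not np.isfinite(lp) or n1 == 0:
            return lp
        spec_try = KernelSpec(u0=u0_new, w0=w0, jitter=kernel.effective_jitter)
        Ktry = kernel_matrix(X1, spec_try)
        try:
            c = cho_factor(Ktry, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        diff = state.eta1 - m1
        return lp - float(np.sum(np.log(np.diag(c[0])))) - 0.5 * float(
            diff @ cho_solve(c, diff))

    w0_cur = state.w0
    w0_prop = w0_cur * np.exp(step * rng.standard_normal())
    log_acc = log_post_w0(w0_prop) - log_post_w0(w0_cur) + np.log(w0_prop / w0_cur)
    accepted = np.log(rng.random()) <= log_acc
    return u0_new, (w0_prop if accepted else w0_cur), bool(accepted)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_state(data: SelectionDataset, K11, m1, spec: MixingSpec, mode: str,
                kernel: KernelSpec, rng) -> ModelState:
    n, n1, q = data.n, data.n1, data.q
    # probit-style start for gamma: linear fit of s on v, mapped through the
    # normal quantile of the fitted selection probabilities
    if mode == "rsgpr" and n > 0:
        beta, *_ = np.linalg.lstsq(data.V, data.s.astype(float), rcond=None)
        p_hat = np.clip(data.V @ beta, 0.02, 0.98)
        gamma, *_ = np.linalg.lstsq(data.V, ndtri(p_hat), rcond=None)
    else:
        gamma = np.zeros(q)
    if n1 > 0:
        var_y = float(np.var(data.y1)) if n1 > 1 else 1.0
        var_y = max(var_y, 1e-8)
        A = K11 + var_y * np.eye(n1)
        c = cho_factor(A, lower=True)
        eta1 = K11 @ cho_solve(c, data.y1) + var_y * cho_solve(c, m1)
        tau2 = float(np.var(data.y1 - eta1)) if n1 > 1 else 1.0
        tau2 = max(tau2, 1e-6)
    else:
        eta1 = np.empty(0)
        tau2 = 1.0
    omega = np.ones(n)
    Vg = data.V @ gamma if q else np.zeros(n)
    z = np.empty(n)
    if n1 > 0:
        z[:n1] = sample_lower_truncated(Vg[:n1], 1.0, 0.0, rng)
    if n1 < n:
        z[n1:] = sample_upper_truncated(Vg[n1:], 1.0, 0.0, rng)
    return ModelState(eta1=eta1, zeta=0.0, tau2=tau2, gamma=np.asarray(gamma),
                      z=z, omega=omega, u0=kernel.u0, w0=kernel.w0)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_gibbs(data: SelectionDataset, kernel: KernelSpec, priors: PriorSpec,
              spec: MixingSpec, config: ChainConfig, mode: str = "rsgpr",
              mean: MeanSpec | None = None, predict: bool = True,
              predict_X: Optional[np.ndarray] = None) -> PosteriorChains:
    """Run the Gibbs/Metropolis sampler and return retained, thinned draws.

    Parameters
    ----------
    mode : {"rsgpr", "gpr_baseline"}
        ``rsgpr`` fits the full selection model; ``gpr_baseline`` pins the
        selection correlation to zero and fits a (robust) GP regression to
        the selected records only.
    predict, predict_X
        When ``predict`` is true, regression-function and outcome draws are
        generated at ``predict_X`` (default: the unselected inputs) at each
        retained iteration.
    """
    if mode not in ("rsgpr", "gpr_baseline"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = MixingSpec.degenerate() if spec is None else spec
    mean = MeanSpec() if mean is None else mean
    rng = np.random.default_rng(config.seed)

    work = data if mode == "rsgpr" else data.selected_only()
    n1 = work.n1
    y1 = work.y[:n1]
    X1 = work.X1
    m1 = mean(X1) if n1 > 0 else np.empty(0)
    K11 = kernel_matrix(X1, kernel) if n1 > 0 else np.empty((0, 0))
    if n1 > 0:
        cK = cho_factor(K11, lower=True)
        K11_inv = cho_solve(cK, np.eye(n1))
    else:
        K11_inv = np.empty((0, 0))

    if predict_X is None:
        predict_X = data.X2 if data.n > data.n1 else None
    do_predict = predict and predict_X is not None and n1 > 0 and len(predict_X) > 0
    if do_predict:
        X2 = np.atleast_2d(np.asarray(predict_X, dtype=float))
        if X2.shape[1] != data.p:
            X2 = X2.T
        from .predict import KernelBlocks  # local import avoids a cycle
        blocks = KernelBlocks.from_kernel(X1, X2, kernel, mean)
    n2 = X2.shape[0] if do_predict else 0

    state = _init_state(work, K11, m1, spec, mode, kernel, rng)
    if config.fix_tau2 is not None:
        state.tau2 = float(config.fix_tau2)

    R = config.n_retained
    out = PosteriorChains(
        eta1=np.empty((R, n1)), zeta=np.empty(R), tau2=np.empty(R),
        gamma=np.empty((R, work.q)), u0=np.empty(R), w0=np.empty(R),
        eta2=np.empty((R, n2)) if do_predict else None,
        y2=np.empty((R, n2)) if do_predict else None,
        X1=X1.copy() if n1 > 0 else None,
        X2=X2.copy() if do_predict else None,
        meta={
            "mode": mode, "seed": config.seed, "n_burn": config.n_burn,
            "n_keep_raw": config.n_keep_raw, "thin": config.thin,
            "mixing": {"kind": spec.kind, "nu": spec.nu},
            "kernel": {"u0": kernel.u0, "w0": kernel.w0,
                       "jitter": kernel.effective_jitter},
            "priors": {"theta0": priors.theta0, "sigma0": priors.sigma0,
                       "c": priors.c, "d": priors.d,
                       "Omega0": priors.Omega0, "gamma0": priors.gamma0,
                       "sample_kernel_hyper": priors.sample_kernel_hyper},
            "n": data.n, "n1": data.n1,
        },
    )

    total = config.n_burn + config.n_keep_raw
    kept = 0
    kernel_cur = kernel
    w0_step = config.w0_step
    w0_acc = 0
    w0_tries = 0
    for it in range(total):
        delta = spec.delta_of(state.omega)
        delta1 = delta[:n1]
        if mode == "rsgpr":
            z_C = state.z - work.V @ state.gamma
            z_C1 = z_C[:n1]
        else:
            z_C1 = np.zeros(n1)

        # eta
        if n1 > 0:
            e_mean, U = eta_params(K11_inv, m1, y1, state.zeta, z_C1, state.tau2, delta1)
            state.eta1 = e_mean + solve_triangular(
                U, rng.standard_normal(n1), lower=False, check_finite=False)

        # tau2 (and zeta in full mode)
        if config.fix_tau2 is None:
            state.tau2 = cond_tau2(state, y1, state.eta1, z_C1, delta1, priors, rng,
                                   include_zeta=(mode == "rsgpr"))
        if mode == "rsgpr":
            state.zeta = cond_zeta(state, y1, state.eta1, z_C1, delta1, priors, rng)
            state.z = cond_z(state, work, delta, rng)
            state.gamma = cond_gamma(state, work, delta, priors, rng)

        # mixing scales
        state.omega = cond_omega(state, work, spec, rng,
                                 include_selection=(mode == "rsgpr"),
                                 mh_step=config.omega_step)

        # kernel hyperparameters (opt-in)
        if priors.sample_kernel_hyper:
            u0_new, w0_new, acc = cond_kernel_hyper(
                state, X1, m1, priors, kernel_cur, rng, step=w0_step)
            w0_tries += 1
            w0_acc += int(acc)
            if config.adapt and it < config.n_burn and w0_tries % 50 == 0:
                rate = w0_acc / 50.0
                if rate < 0.2:
                    w0_step *= 0.7
                elif rate > 0.5:
                    w0_step *= 1.4
                w0_acc = 0
            state.u0, state.w0 = float(u0_new), float(w0_new)
            kernel_cur = KernelSpec(u0=state.u0, w0=state.w0, jitter=kernel.jitter,
                                    form=kernel.form, func=kernel.func)
            K11 = kernel_matrix(X1, kernel_cur) if n1 > 0 else K11
            if n1 > 0:
                cK = cho_factor(K11, lower=True)
                K11_inv = cho_solve(cK, np.eye(n1))

        if not (np.isfinite(state.tau2) and np.isfinite(state.zeta)):
            raise RuntimeError(
                f"non-finite sampler state at iteration {it}: "
                f"tau2={state.tau2}, zeta={state.zeta}")

        k = it - config.n_burn
        if k >= 0 and (k + 1) % config.thin == 0:
            out.eta1[kept] = state.eta1
            out.zeta[kept] = state.zeta
            out.tau2[kept] = state.tau2
            out.gamma[kept] = state.gamma
            out.u0[kept] = state.u0
            out.w0[kept] = state.w0
            if do_predict:
                if priors.sample_kernel_hyper:
                    blocks = KernelBlocks.from_kernel(X1, X2, kernel_cur, mean)
                eta2 = blocks.conditional_draw(state.eta1, rng)
                omega2 = spec.draw_omega(n2, rng)
                delta2 = spec.delta_of(omega2)
                sig2 = state.sigma2 if mode == "rsgpr" else state.tau2
                out.eta2[kept] = eta2
                out.y2[kept] = eta2 + np.sqrt(sig2 * delta2) * rng.standard_normal(n2)
            kept += 1
    assert kept == R
    return out
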