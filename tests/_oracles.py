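"""Independent oracles shared by the unit and acceptance tests.

Everything here deliberately avoids the code paths it checks: grid/griddy
posteriors are computed by brute-force quadrature on dense grids, truncated
multivariate draws by rejection from the untruncated law, and the Geweke
joint-distribution test compares the Gibbs transition against independent
prior simulation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

import gpselect as g
from gpselect import sampler as S


# ---------------------------------------------------------------------------
# grid posteriors for the full conditionals
# ---------------------------------------------------------------------------

def grid_moments(grid, log_density):
    """Mean and variance of a 1-D density known up to a constant on a grid."""
    lp = log_density - log_density.max()
    w = np.exp(lp)
    w /= np.trapezoid(w, grid)
    mean = np.trapezoid(grid * w, grid)
    var = np.trapezoid((grid - mean) ** 2 * w, grid)
    return mean, var


def eta_grid_posterior_1d(y, m, k11, zeta, z_c, tau2, delta, span=8.0, n=4001):
    """Brute-force 1-point posterior of eta: N(m, k11) prior x normal lik."""
    grid = np.linspace(m - span * np.sqrt(k11), m + span * np.sqrt(k11), n)
    lp = (-0.5 * (grid - m) ** 2 / k11
          - 0.5 * (y - grid - zeta * z_c) ** 2 / (delta * tau2))
    return grid_moments(grid, lp)


def zeta_grid_posterior(y, eta, z_c, delta, tau2, theta0, sigma0, span=10.0, n=8001):
    """1-D grid posterior of zeta for a single selected record."""
    sd0 = np.sqrt(sigma0 * tau2)
    grid = theta0 + np.linspace(-span, span, n) * sd0
    lp = (-0.5 * (grid - theta0) ** 2 / (sigma0 * tau2)
          - 0.5 * (y - eta - grid * z_c) ** 2 / (delta * tau2))
    return grid_moments(grid, lp)


def gamma_grid_posterior(data, z, eta1, zeta, tau2, delta, gamma0, omega0,
                         span=10.0, n=6001):
    """1-D grid posterior of a scalar selection coefficient."""
    grid = np.linspace(gamma0 - span, gamma0 + span, n)
    v = data.V[:, 0]
    n1 = data.n1
    lp = -0.5 * (grid - gamma0) ** 2 / omega0
    for i in range(data.n):
        lp = lp - 0.5 * (z[i] - v[i] * grid) ** 2 / delta[i]
    for i in range(n1):
        zc = z[i] - v[i] * grid
        lp = lp - 0.5 * (data.y[i] - eta1[i] - zeta * zc) ** 2 / (delta[i] * tau2)
    return grid_moments(grid, lp)


# ---------------------------------------------------------------------------
# truncated-MVN rejection sampler (stochastic-representation oracle)
# ---------------------------------------------------------------------------

def box_truncated_mvn(cov, lower, n_draws, rng, batch=200000, max_batches=2000):
    """Rejection draws of N(0, cov) conditioned on every component >= lower."""
    L = np.linalg.cholesky(cov)
    d = cov.shape[0]
    lower = np.broadcast_to(np.asarray(lower, float), (d,))
    out = []
    got = 0
    for _ in range(max_batches):
        x = rng.standard_normal((batch, d)) @ L.T
        keep = (x >= lower).all(axis=1)
        if keep.any():
            out.append(x[keep])
            got += int(keep.sum())
        if got >= n_draws:
            break
    if got < n_draws:
        raise RuntimeError("rejection sampler starved; choose milder thresholds")
    return np.concatenate(out)[:n_draws]


def representation_mc_gap(y, K11, m1, scale, alphas, n_draws, rng):
    """Monte-Carlo posterior-mean gap from the conditional-posterior
    stochastic representation (normal-error case, delta = 1)."""
    from gpselect.bias import BiasOperators

    ops = BiasOperators.build(y, K11, m1, scale, alphas, delta=1.0)
    w1 = box_truncated_mvn(ops.Omega2, ops.beta, n_draws, rng)
    draws = ops.theta1 + (ops.Gamma @ np.linalg.solve(ops.Omega2, w1.T)).T
    # W2 has mean zero; omitting it changes no means and shrinks MC error
    return draws.mean(axis=0) - ops.theta1, draws.std(axis=0) / np.sqrt(n_draws)


# ---------------------------------------------------------------------------
# quadrature CDF of the selected-outcome density
# ---------------------------------------------------------------------------

def skew_smn_cdf_on_grid(eta, scale, alpha, spec, lo, hi, n=20001):
    """(grid, cdf) of the selected-outcome law by trapezoid integration."""
    grid = np.linspace(lo, hi, n)
    pdf = np.exp(g.skew_smn_logpdf(grid, eta, scale, alpha, spec))
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    return grid, cdf


def conditional_mean_y_given_selected(eta, scale, alpha, spec, span=60.0, n=60001):
    """E[y | s=1] by quadrature of y * h(y|s=1)."""
    sd = np.sqrt(scale.sigma2) * (4.0 if not spec.is_degenerate else 1.5)
    grid = np.linspace(eta - span * sd / 6, eta + span * sd / 6, n)
    pdf = np.exp(g.skew_smn_logpdf(grid, eta, scale, alpha, spec))
    z = np.trapezoid(pdf, grid)
    return float(np.trapezoid(grid * pdf, grid) / z)


# ---------------------------------------------------------------------------
# Geweke joint-distribution harness
# ---------------------------------------------------------------------------

class GewekeHarness:
    """Compare prior simulation with the successive-conditional simulator.

    The model dimension stays fixed (n inputs on a grid, intercept-only
    selection); the Gibbs transition reuses the package's conditional
    samplers, with the unselected part of the regression function refreshed
    from its conditional GP prior so the state dimension never changes.
    """

    def __init__(self, n=12, nu=5.0, seed=42):
        self.n = n
        self.x = (np.arange(n) + 0.5) / n
        self.V = np.ones((n, 1))
        self.kern = g.KernelSpec(u0=1.5, w0=30.0)
        self.K = g.kernel_matrix(self.x[:, None], self.kern)
        self.L = np.linalg.cholesky(self.K)
        self.pri = g.PriorSpec(theta0=0.3, sigma0=0.5, c=5.0, d=4.0, Omega0=0.8)
        self.spec = g.MixingSpec.gamma_t(nu)
        self.rng = np.random.default_rng(seed)

    def prior_draw(self):
        rng, pri = self.rng, self.pri
        tau2 = pri.d / rng.gamma(pri.c)
        zeta = pri.theta0 + np.sqrt(pri.sigma0 * tau2) * rng.standard_normal()
        gam = np.array([rng.normal(0.0, np.sqrt(0.8))])
        eta = self.L @ rng.standard_normal(self.n)
        return eta, zeta, tau2, gam

    def forward(self, eta, zeta, tau2, gam):
        rng = self.rng
        om = self.spec.draw_omega(self.n, rng)
        d = self.spec.delta_of(om)
        z = self.V @ gam + np.sqrt(d) * rng.standard_normal(self.n)
        s = (z >= 0).astype(int)
        zc = z - self.V @ gam
        y = np.where(s == 1,
                     eta + zeta * zc + np.sqrt(d * tau2) * rng.standard_normal(self.n),
                     np.nan)
        return om, z, s, y

    def gibbs_cycle(self, eta, zeta, tau2, gam, om, z, s, y):
        rng, n = self.rng, self.n
        idx = np.argsort(1 - s, kind="stable")
        n1 = int(s.sum())
        ds = g.SelectionDataset(X=self.x[idx][:, None], V=self.V[idx], s=s[idx],
                                y=y[idx], order=idx)
        st = S.ModelState(eta1=eta[idx][:n1], zeta=zeta, tau2=tau2, gamma=gam,
                          z=z[idx], omega=om[idx], u0=self.kern.u0, w0=self.kern.w0)
        delta = self.spec.delta_of(st.omega)
        d1 = delta[:n1]
        zc1 = (st.z - ds.V @ st.gamma)[:n1]
        Ksel = self.K[np.ix_(idx[:n1], idx[:n1])]
        if n1 > 0:
            Kinv = np.linalg.inv(Ksel + 1e-10 * np.eye(n1))
            st.eta1 = S.cond_eta(st, ds.y[:n1], Kinv, np.zeros(n1), d1, zc1, rng)
        if 0 < n1 < n:
            blocks = g.KernelBlocks.from_blocks(
                Ksel, self.K[np.ix_(idx[:n1], idx[n1:])],
                self.K[np.ix_(idx[n1:], idx[n1:])],
                np.zeros(n1), np.zeros(n - n1), jitter=1e-10)
            eta_un = blocks.conditional_draw(st.eta1, rng)
        elif n1 == 0:
            eta_un = self.L @ rng.standard_normal(n)
        else:
            eta_un = np.empty(0)
        st.tau2 = S.cond_tau2(st, ds.y[:n1], st.eta1, zc1, d1, self.pri, rng)
        st.zeta = S.cond_zeta(st, ds.y[:n1], st.eta1, zc1, d1, self.pri, rng)
        st.z = S.cond_z(st, ds, delta, rng)
        st.gamma = S.cond_gamma(st, ds, delta, self.pri, rng)
        st.omega = S.cond_omega(st, ds, self.spec, rng)
        full_eta = np.empty(n)
        if n1 == 0:
            full_eta = eta_un
        else:
            full_eta[idx[:n1]] = st.eta1
            if n1 < n:
                full_eta[idx[n1:]] = eta_un
        z_o = np.empty(n)
        z_o[idx] = st.z
        om_o = np.empty(n)
        om_o[idx] = st.omega
        return full_eta, st.zeta, st.tau2, st.gamma, om_o, z_o

    @staticmethod
    def _stats(eta, zeta, tau2, gam):
        em = eta.mean()
        return [zeta, zeta ** 2, tau2, tau2 ** 2, gam[0], gam[0] ** 2, em, em ** 2]

    def run(self, n_cycles=30000):
        """Returns z-scores of the moment comparisons (8 test functions)."""
        mc = np.array([self._stats(*self.prior_draw()) for _ in range(n_cycles)])
        eta, zeta, tau2, gam = self.prior_draw()
        sc = np.empty_like(mc)
        for t in range(n_cycles):
            om, z, s, y = self.forward(eta, zeta, tau2, gam)
            eta, zeta, tau2, gam, om, z = self.gibbs_cycle(
                eta, zeta, tau2, gam, om, z, s, y)
            sc[t] = self._stats(eta, zeta, tau2, gam)

        def bm_se(a, nb=40):
            m = len(a) // nb
            bm = a[: m * nb].reshape(nb, m).mean(axis=1)
            return bm.std(ddof=1) / np.sqrt(nb)

        zs = []
        for j in range(mc.shape[1]):
            se = np.sqrt(mc[:, j].std(ddof=1) ** 2 / n_cycles + bm_se(sc[:, j]) ** 2)
            zs.append((mc[:, j].mean() - sc[:, j].mean()) / se)
        return np.array(zs)


def kernel_hyper_geweke(n_cycles=20000, n1=6, seed=7):
    """Prior-stationarity z-scores for the (u0, w0 | eta) block: draw eta
    from its GP prior given the current hyperparameters, then update
    (u0, w0) with the package's conditional; the hyperparameter marginals
    must stay at their priors."""
    rng = np.random.default_rng(seed)
    x = (np.arange(n1) + 0.5) / n1
    pri = g.PriorSpec(a=4.0, b=3.0, c_w=0.0, d_w=10.0, sample_kernel_hyper=True)
    kern0 = g.KernelSpec(u0=1.0, w0=20.0, jitter=1e-10)

    def prior_hyper():
        u0 = pri.b / rng.gamma(pri.a)
        w0 = abs(stats.cauchy.rvs(loc=pri.c_w, scale=pri.d_w,
                                  random_state=rng))
        return u0, max(w0, 1e-3)

    mc = np.array([prior_hyper() for _ in range(n_cycles)])
    u0, w0 = prior_hyper()
    sc = np.empty((n_cycles, 2))
    st = S.ModelState(eta1=np.zeros(n1), zeta=0.0, tau2=1.0,
                      gamma=np.zeros(1), z=np.zeros(n1), omega=np.ones(n1),
                      u0=u0, w0=w0)
    for t in range(n_cycles):
        kern = g.KernelSpec(u0=st.u0, w0=st.w0, jitter=1e-10)
        K = g.kernel_matrix(x[:, None], kern)
        st.eta1 = np.linalg.cholesky(K) @ rng.standard_normal(n1)
        u0n, w0n, _ = S.cond_kernel_hyper(st, x[:, None], np.zeros(n1), pri,
                                          kern, rng, step=1.0)
        st.u0, st.w0 = float(u0n), float(w0n)
        sc[t] = [st.u0, st.w0]

    def bm_se(a, nb=40):
        m = len(a) // nb
        bm = a[: m * nb].reshape(nb, m).mean(axis=1)
        return bm.std(ddof=1) / np.sqrt(nb)

    # half-Cauchy has no mean: compare medians for w0, means for u0
    z_u0 = (mc[:, 0].mean() - sc[:, 0].mean()) / np.sqrt(
        mc[:, 0].std(ddof=1) ** 2 / n_cycles + bm_se(sc[:, 0]) ** 2)
    med_mc, med_sc = np.median(mc[:, 1]), np.median(sc[:, 1])
    iqr = np.subtract(*np.percentile(mc[:, 1], [75, 25]))
    z_w0 = (med_mc - med_sc) / (1.5 * iqr / np.sqrt(n_cycles / 10))
    return np.array([z_u0, z_w0])
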