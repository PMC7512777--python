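# Methods

## The model

`gpselect` fits a nonparametric regression whose outcome is observed only
when a correlated latent selection score is positive — the incidental
truncation (Heckman-type) setting, with the regression function given a
Gaussian-process prior and the errors given a scale-mixture-of-normals
(SMN) law for robustness.

For records `i = 1..n` with outcome covariates `x_i` and selection
covariates `v_i`:

    y_i = eta(x_i) + eps_i          observed iff  s_i = 1{z_i >= 0}
    z_i = v_i' gamma + e_i
    (eps_i, e_i) | omega_i  ~  N2(0, delta(omega_i) * Sigma),  omega_i ~ G
    Sigma = [[sigma^2, rho*sigma], [rho*sigma, 1]]
    eta ~ GP(m, K),  K(x, x') = u0 * exp(-(w0/2) ||x - x'||^2)

The GP prior is the maximum-entropy prior for a regression function whose
mean and covariance functions are the only stated prior information; with
mean/covariance constraints the MaxEnt distribution is Gaussian, which is
the information-theoretic footing for using GP regression here.

Mixing laws implemented: the degenerate law `delta == 1` (bivariate normal
errors; "SGPRN" in the model-name shorthand), gamma mixing
`omega ~ Gamma(nu/2, nu/2)` with `delta = 1/omega` (bivariate Student-t
errors, "SGPRt<nu>"), and a custom hook (`MixingSpec.custom`) accepting a
user `delta`, density, sampler and optional quantile function. Logit,
stable, slash and exponential-power mixing are *not* shipped; the custom
hook admits them but they are untested.

When `rho != 0` the selected outcomes are missing not at random: the law
of `y | s = 1` is a skew-SMN distribution (a normal density times a
conditional selection probability, mixed over `omega`). Fitting a plain GP
regression to the selected records then biases the posterior mean of
`eta` — the bias has sign opposite to `rho` and grows with `|rho|` and with
the truncation thresholds — and distorts the marginal effect of any
covariate shared by both equations. The `bias` module implements both gaps
in closed form and exports them as curves.

A note on the posterior-mean gap: we derive it directly from the
stochastic representation of the conditional posterior
(`gap = Gamma Omega2*^-1 xi = -rho*sigma * Omega1* [rho^2 Omega1* +
sigma^2 (1-rho^2) I]^-1 xi`, with `xi` the componentwise truncated-normal
means). This form is exactly zero at `rho = 0`, is numerically stable for
all `|rho| < 1` (the bracket is always positive definite), and is verified
in the tests against a Monte-Carlo evaluation of the same representation.
The componentwise `xi` treats the truncated Gaussian component through its
marginals; for the near-diagonal `Omega2*` matrices arising from smooth
kernels the induced error is well below the Monte-Carlo tolerance used in
the tests. The marginal-effect gap is likewise derived by differentiating
the quadrature conditional mean `E[y | s=1]` and is checked against a
finite-difference oracle; in the normal-error case it reduces to the
familiar `gamma_k rho sigma (alpha*lambda - lambda^2)` with `lambda` the
normal hazard at `alpha`.

## Estimation

The sampler works in the conjugate parametrization `zeta = rho*sigma`,
`tau2 = sigma^2 (1-rho^2)` (the inverse map automatically keeps
`|rho| < 1`), with priors

    eta_n1 ~ N(m1, K11),  zeta | tau2 ~ N(theta0, sigma0*tau2),
    tau2 ~ IG(c, d),      gamma ~ N(gamma0, Omega0)

and data augmentation by the latent scores `z` and mixing scales `omega`.
Every full conditional is then standard: multivariate normal for `eta_n1`
(precision `K11^-1 + D1^-1/tau2`), inverse-gamma for `tau2`, normal for
`zeta` and `gamma`, one-sided truncated normals for `z` (the sign
constraint `z_i >= 0 iff s_i = 1` is exact by construction), and — for
gamma mixing — conjugate gamma laws for `omega` (selected records combine
the outcome and score residuals with shape `(nu+2)/2`; unselected records
use the score only with shape `(nu+1)/2`). Custom mixing laws fall back to
one log-normal random-walk Metropolis step per record.

Defaults (used throughout the simulation harness) are the diffuse choices
`theta0 = 0, sigma0 = 10, c = d = 0.001, gamma0 = 0, Omega0 = 10 I`, and a
sampling plan of 5000 burn-in iterations plus 15000 raw draws thinned by 5
(3000 retained). Blocks are updated in the order eta, tau2, zeta, z,
gamma, omega, kernel hyperparameters; Gibbs validity does not depend on
the order.

Design choices worth knowing:

* **Kernel hyperparameters are fixed by default.** Sampling them is
  available (`PriorSpec.sample_kernel_hyper`): `u0` has a conjugate
  inverse-gamma update given the correlation matrix `R(w0)`
  (`K11 = u0 R(w0)`), and `w0` takes one log-scale random-walk Metropolis
  step targeting the GP prior times a half-Cauchy hyperprior, with the
  step size adapted to a 20–50% acceptance rate during burn-in and frozen
  afterwards. For the simulation designs we fix `(u0, w0) = (250, 25)`:
  amplitude of the order of the outcome variance and correlation length
  `1/sqrt(w0) = 0.2`, enough to resolve the `sin(10x)` oscillation of the
  design function without chasing noise. A pilot scan showed the
  replication results are insensitive to this choice over two orders of
  magnitude in either hyperparameter.
* **Initialization**: `gamma` from a probit-style least-squares fit of `s`
  on `v`; `eta` from the closed-form GP posterior using the selected
  outcomes; `zeta = 0`; `tau2` the variance of the residuals of that pilot
  fit; `omega = 1`; `z` from its truncated prior.
* **Truncated-normal draws** use the inverse-CDF transform in the bulk and
  Robert's translated-exponential rejection beyond 5 standardized units —
  exact in distribution, no clipping, stable for thresholds beyond +-8.
* **Jitter**: `1e-8 * u0` on every Gram-matrix diagonal (squared-
  exponential matrices on dense 1-D designs are numerically singular
  without it); all solves go through Cholesky factorizations.
* **Numerical guards**: the observed-data likelihood and all tail
  probabilities are computed in log space (`log_ndtr` / Student-t log
  tails); mixing integrals use 64-node Gauss–Legendre quadrature mapped
  through the quantile function of `G` (about 1e-5 log-density accuracy;
  the node count is configurable), with a deterministic Monte-Carlo
  fallback when no quantile function exists.
* **`gpr_baseline` mode** pins `zeta = 0` and drops the selection
  equation, i.e. fits an ordinary (robust) GP regression to the selected
  records only — the selection-naive comparator.

Prediction at unselected or new inputs conditions the joint GP prior on
each retained draw of `eta_n1` (mean `m2 + K21 K11^-1 (eta_n1 - m1)`,
covariance the Schur complement), then adds SMN noise with fresh prior
mixing draws (test-point scales are not identified by data). Because the
training draws come from the selection-aware posterior, the Monte-Carlo
average of these draws is the bias-corrected prediction. Interval
summaries use equal-tail 2.5/97.5 percentiles with linear interpolation
between order statistics.

Model comparison uses DIC computed from the *observed-data* likelihood
(latent scores and mixing scales integrated out) with Spiegelhalter's
`pD = Dbar - D(theta_bar)`; augmented-data DIC is ill-defined under data
augmentation. `theta_bar` takes posterior means of `(eta_n1, zeta, tau2,
gamma)` jointly.

## Synthetic designs and what they do (not) show

The generator reproduces three error laws around the common design
`y = 50x + 5 sin(10x) + eps`, `x in (0,1)`, intercept-only selection
`z = gamma + e` with `gamma = 0` (half the outcomes selected on average),
`rho = 0.5`, `sigma = 3`, `n = 300`: bivariate normal (Model 1), shared
gamma-mixing Student-t10 (Model 2), and a five-component normal mixture
with weights (0.4, 0.2, 0.2, 0.1, 0.1) over outcome-variance factors
(1, 2, 4, 8, 16) — marginal outcome variance 36 (Model 3). Covariates are
uniform by default; the replication harness uses an equally spaced grid
and whole-dataset rejection to hit exactly `n1 = 150` selected records,
which preserves the model law. These designs exercise selection bias and
heavy-tail robustness, but not covariate-dependent selection (`v` is an
intercept), multivariate `x`, or model misspecification in the mean — so
passing tests speak to the estimator's behaviour under the stated law,
not to real-data performance in general.

Identification is deliberately weak in these designs: with intercept-only
selection and a flexible nonparametric mean there is no exclusion
restriction, so `rho` is identified only through the distributional shape
of the selected residuals. Posterior distributions of `rho` are
correspondingly wide, posterior means of `rho` are attenuated toward zero
relative to the true 0.5, and posterior means of `sigma` carry an upward
Jensen-type inflation from the wide `(zeta, tau2)` posterior. The
replication harness reproduces these qualitative signatures; its
quantitative reference points and the reduced problem sizes it runs at
(M = 20 replicates, 1000 burn-in + 3000 raw draws; DIC averaged over 3
datasets) are stated in the README.

## Validation strategy

* Full conditionals are checked against brute-force grid posteriors on
  one/two-record instances, and against closed forms where they exist.
* The whole Gibbs cycle passes a Geweke joint-distribution test
  (marginal-conditional vs successive-conditional simulation, first two
  moments at 3 sigma, n = 12 with t5 mixing); the kernel-hyperparameter
  block passes its own prior-stationarity version.
* The skew-SMN density, the two-stage representation of a selected
  outcome, and the analytic bias formulas are cross-checked against each
  other by quadrature, KS tests and Monte-Carlo sampling oracles.
* With the selection correlation pinned to zero and the noise variance
  held fixed, the Gibbs posterior of `eta` reproduces the closed-form GP
  posterior.

## Known limitations

* Only degenerate and gamma mixing are first-class; the custom hook is
  provided but untested against reference laws.
* DIC is only defined here for selection-model chains (the baseline mode
  drops `gamma` from the model).
* The componentwise `xi` in the analytic bias is exact only for diagonal
  truncation covariance; the error is negligible for smooth kernels but
  grows with strong equicorrelation at small `n1`.
* Single-chain inference: convergence diagnostics beyond batch-means
  Monte-Carlo error are left to downstream tooling.
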