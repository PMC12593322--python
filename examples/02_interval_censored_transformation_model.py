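"""Fit the semiparametric transformation model to interval-censored times.

Simulates event times from a proportional-odds model (rho = 1) with two
covariates, censors them through a visit process, fits the model by the
Poisson-augmented EM at the true rho, and compares the estimated covariate
effects and survival curve with the truth.
"""

import numpy as np

from trisurv import ISplineBasis, SurvivalData, fit_em, survival_prob, transform_G

rng = np.random.default_rng(1)
n = 600
beta_true = np.array([0.5, -0.5])
rho = 1.0

Z = np.column_stack([rng.binomial(1, 0.5, n).astype(float),
                     rng.standard_normal(n)])
eta = Z @ beta_true
zeta = rng.gamma(1 / rho, rho, n)          # frailty with mean 1, variance rho
T = np.sqrt(-4 * np.log(rng.uniform(size=n)) / (zeta * np.exp(eta)))

# visits every Uniform(0.1, 0.5); administrative cutoff at t = 4
visits = np.cumsum(rng.uniform(0.1, 0.5, (n, 30)), axis=1)
L, R = np.zeros(n), np.full(n, np.inf)
for i in range(n):
    v = visits[i][visits[i] <= 4.0]
    k = np.searchsorted(v, T[i])
    if k == 0:
        L[i], R[i] = 0.0, v[0]
    elif k == len(v):
        L[i], R[i] = v[-1], np.inf
    else:
        L[i], R[i] = v[k - 1], v[k]

data = SurvivalData(L, R, Z)
print(f"censoring: {data.is_left.mean():.0%} left, "
      f"{data.is_interval.mean():.0%} interval, {data.is_right.mean():.0%} right")

basis = ISplineBasis.from_data(L, R)       # cubic I-splines, 4 interior knots
fit = fit_em(data, basis, rho=rho, tol=1e-4, max_iter=2000)
print(f"EM converged in {fit.n_iter} iterations; "
      f"beta-hat = {np.round(fit.params.beta, 3)} (truth {beta_true})")

t = np.array([1.0, 2.0])
S_hat = survival_prob(fit.params, basis, t, Z=np.array([1.0, 0.0]))
S_true = np.exp(-transform_G(t ** 2 * np.exp(0.5) / 4, rho))
print(f"S(t | Z=(1,0)) at t={t}: fitted {np.round(S_hat, 3)}, "
      f"true {np.round(S_true, 3)}")
print("the sieve EM recovers both the covariate effects and the baseline "
      "survival shape from intervals alone")
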