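import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from trisurv.em import (AugmentationRates, PenaltySpec, _Prepared, _QContext,
                        augmentation_rates, blocks_of, e_step, fit_em,
                        fit_path, lambda_max, update_beta, update_gamma,
                        update_omega)
from trisurv.survival import ISplineBasis, ModelParams, SurvivalData


def make_data(n=40, seed=0, q_img=0, rho=0.0):
    """Small interval-censored data set; optional synthetic 'image' scores."""
    rng = np.random.default_rng(seed)
    Z = np.column_stack([rng.binomial(1, 0.5, n).astype(float),
                         rng.standard_normal(n)])
    xi = rng.standard_normal((n, q_img)) if q_img else None
    eta = Z @ np.array([0.5, -0.5])
    if xi is not None:
        eta = eta + 0.4 * xi[:, 0]
    zeta = rng.gamma(1 / rho, rho, n) if rho > 0 else np.ones(n)
    T = np.sqrt(-4 * np.log(rng.uniform(size=n)) / (zeta * np.exp(eta)))
    visits = np.cumsum(rng.uniform(0.1, 0.5, (n, 12)), axis=1)
    L = np.zeros(n)
    R = np.full(n, np.inf)
    for i in range(n):
        v = visits[i][visits[i] <= 2.5]
        k = np.searchsorted(v, T[i])
        if k == 0:
            L[i], R[i] = 0, v[0]
        elif k == len(v):
            L[i], R[i] = v[-1], np.inf
        else:
            L[i], R[i] = v[k - 1], v[k]
    return SurvivalData(L, R, Z, xi=xi)


@pytest.fixture(scope="module")
def basis_and_data():
    data = make_data(n=40, seed=1)
    return ISplineBasis.from_data(data.L, data.R), data


class TestAugmentationRates:
    def test_class_structure_and_sums(self, basis_and_data):
        basis, data = basis_and_data
        rng = np.random.default_rng(2)
        params = ModelParams(rng.uniform(0.05, 0.3, basis.J),
                             np.array([0.3, -0.2]), None, rho=0.5)
        rates = augmentation_rates(params, data, basis)
        assert (rates.mu >= 0).all() and (rates.eta >= 0).all()
        assert np.all(rates.mu[data.is_right] == 0)
        assert np.all(rates.eta[data.is_left] == 0)
        # interval records: sum_j eta_ij = (Lam(R) - Lam(L)) e^eta
        eta_lin = params.linear_predictor(data.Z)
        ii = np.nonzero(data.is_interval)[0]
        lamL = basis.cumhaz(params.omega, data.L[ii])
        lamR = basis.cumhaz(params.omega, np.minimum(data.R[ii], basis.tmax))
        np.testing.assert_allclose(rates.eta[ii].sum(axis=1),
                                   (lamR - lamL) * np.exp(eta_lin[ii]), atol=1e-10)


class TestEStep:
    def test_rho_zero_unit_frailty(self, basis_and_data):
        basis, data = basis_and_data
        params = ModelParams(np.full(basis.J, 0.15), np.zeros(2), None, rho=0.0)
        rates = augmentation_rates(params, data, basis)
        mom = e_step(rates, 0.0, dL=data.is_left, dI=data.is_interval,
                     dR=data.is_right)
        np.testing.assert_allclose(mom.Ezeta, 1.0, atol=1e-12)

    def test_left_censored_poisson_identity(self):
        # E[sum_j A_j | A > 0] = m/(1 - e^{-m}) at rho = 0, m = log 2
        m = np.log(2.0)
        mu = np.array([[m / 3, m / 3, m / 3]])
        eta = np.zeros_like(mu)
        mom = e_step(AugmentationRates(mu, eta), 0.0,
                     dL=[True], dI=[False], dR=[False])
        assert abs(mom.EA.sum() - 2 * np.log(2.0)) < 1e-12

    @pytest.mark.parametrize("rho", [0.0, 0.25, 0.5, 1.0, 2.0])
    def test_closed_forms_match_quadrature_oracle(self, rho):
        """Hard gate: the closed-form E-step equals brute-force integration
        over zeta ~ Gamma(1/rho, 1/rho) with exact Poisson conditioning on
        the observed pattern, for 20 random instances per rho."""
        rng = np.random.default_rng(int(rho * 100) + 7)
        for _ in range(20):
            J = 5
            cls = rng.choice(["left", "int", "right"])
            mu = (rng.uniform(0.05, 1.5, J) if cls in ("left", "int")
                  else np.zeros(J))
            if cls == "left":
                et = np.zeros(J)
            else:
                et = rng.uniform(0.05, 1.5, J)
            mom = e_step(AugmentationRates(mu[None], et[None]), rho,
                         dL=[cls == "left"], dI=[cls == "int"],
                         dR=[cls == "right"])
            Ez, EA, EB = _oracle_moments(mu, et, rho, cls)
            assert abs(mom.Ezeta[0] - Ez) < 1e-8
            np.testing.assert_allclose(mom.EA[0], EA, atol=1e-8)
            np.testing.assert_allclose(mom.EB[0], EB, atol=1e-8)


def _oracle_moments(mu_vec, eta_vec, rho, cls):
    """Numeric-integration oracle for the E-step moments."""
    m, e = mu_vec.sum(), eta_vec.sum()
    if cls == "left":
        patt = lambda z: 1 - np.exp(-z * m)
    elif cls == "int":
        patt = lambda z: np.exp(-z * m) * (1 - np.exp(-z * e))
    else:
        patt = lambda z: np.exp(-z * e)
    if rho == 0:
        if cls == "left":
            return 1.0, mu_vec / (1 - np.exp(-m)), np.zeros_like(eta_vec)
        if cls == "int":
            return 1.0, np.zeros_like(mu_vec), eta_vec / (1 - np.exp(-e))
        return 1.0, np.zeros_like(mu_vec), np.zeros_like(eta_vec)
    pdf = gamma_dist(a=1 / rho, scale=rho).pdf
    den = quad(lambda z: patt(z) * pdf(z), 0, np.inf, limit=200)[0]
    Ez = quad(lambda z: z * patt(z) * pdf(z), 0, np.inf, limit=200)[0] / den
    EA = np.zeros_like(mu_vec)
    EB = np.zeros_like(eta_vec)
    if cls == "left":
        # E[A_ij 1(A>0) | zeta] = zeta mu_ij since A_ij > 0 implies A > 0
        EA = mu_vec * quad(lambda z: z * pdf(z), 0, np.inf, limit=200)[0] / den
    elif cls == "int":
        EB = eta_vec * quad(lambda z: z * np.exp(-z * m) * pdf(z),
                            0, np.inf, limit=200)[0] / den
    return Ez, EA, EB


class TestUpdates:
    @pytest.mark.parametrize("rho", [0.0, 0.5])
    def test_omega_star_zeroes_q_gradient(self, rho):
        data = make_data(n=30, seed=3)
        basis = ISplineBasis.from_data(data.L, data.R)
        rng = np.random.default_rng(4)
        params = ModelParams(rng.uniform(0.05, 0.3, basis.J),
                             np.array([0.2, -0.1]), None, rho=rho)
        rates = augmentation_rates(params, data, basis)
        mom = e_step(rates, rho, dL=data.is_left, dI=data.is_interval,
                     dR=data.is_right)
        w_star = update_omega(mom, data, basis, params.beta, None, rho)
        assert (w_star >= 0).all()
        prep = _Prepared(data, basis)
        eta = prep.Z @ params.beta

        def Q_of_omega(w):
            mu = w[None, :] * prep.U * np.exp(eta)[:, None]
            et = w[None, :] * prep.V * np.exp(eta)[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(mom.EA > 0, mom.EA * np.log(np.maximum(mu, 1e-300)), 0.0)
                t2 = np.where(mom.EB > 0, mom.EB * np.log(np.maximum(et, 1e-300)), 0.0)
            return float((-(mu + et) * mom.Ezeta[:, None] + t1 + t2).sum())

        h = 1e-6
        for j in range(basis.J):
            if w_star[j] <= h:
                continue
            wp, wm = w_star.copy(), w_star.copy()
            wp[j] += h
            wm[j] -= h
            grad = (Q_of_omega(wp) - Q_of_omega(wm)) / (2 * h)
            assert abs(grad) < 1e-4

    def test_omega_zero_when_no_subject_loads_basis(self):
        data = SurvivalData(np.array([0.5]), np.array([np.inf]),
                            np.zeros((1, 1)))
        basis = ISplineBasis(interior_knots=[0.2, 0.3, 0.4, 0.45], tmax=0.5)
        params = ModelParams(np.full(basis.J, 0.1), np.zeros(1), None, rho=0.0)
        rates = augmentation_rates(params, data, basis)
        mom = e_step(rates, 0.0, dL=data.is_left, dI=data.is_interval,
                     dR=data.is_right)
        w = update_omega(mom, data, basis, params.beta, None, 0.0)
        # single right-censored subject: no events anywhere
        np.testing.assert_array_equal(w, 0.0)

    def test_beta_step_never_decreases_q(self):
        data = make_data(n=50, seed=5)
        basis = ISplineBasis.from_data(data.L, data.R)
        rng = np.random.default_rng(6)
        for _ in range(5):
            params = ModelParams(rng.uniform(0.05, 0.3, basis.J),
                                 rng.normal(0, 0.5, 2), None, rho=0.3)
            rates = augmentation_rates(params, data, basis)
            mom = e_step(rates, 0.3, dL=data.is_left, dI=data.is_interval,
                         dR=data.is_right)
            prep = _Prepared(data, basis)
            ctx = _QContext(prep, mom)
            q0 = ctx.value(ctx.eta(params.beta, None))
            beta_new = update_beta(mom, data, basis, params.beta, None)
            q1 = ctx.value(ctx.eta(beta_new, None))
            assert q1 >= q0 - 1e-10 * (1 + abs(q0))

    def test_beta_stationary_point_fixed(self):
        data = make_data(n=60, seed=7)
        basis = ISplineBasis.from_data(data.L, data.R)
        fit = fit_em(data, basis, rho=0.0, tol=1e-10, max_iter=3000)
        beta_hat = fit.params.beta
        rates = augmentation_rates(fit.params, data, basis)
        mom = e_step(rates, 0.0, dL=data.is_left, dI=data.is_interval,
                     dR=data.is_right)
        beta_next = update_beta(mom, data, basis, beta_hat, None)
        np.testing.assert_allclose(beta_next, beta_hat, atol=1e-6)

    def test_constant_zero_covariate_coefficient_unmoved(self):
        data = make_data(n=40, seed=8)
        data = SurvivalData(data.L, data.R,
                            np.column_stack([data.Z, np.zeros(len(data))]))
        basis = ISplineBasis.from_data(data.L, data.R)
        fit = fit_em(data, basis, rho=0.0, tol=1e-4)
        assert fit.params.beta[2] == 0.0


class TestGroupLasso:
    def test_kkt_full_shrinkage_at_large_lambda(self):
        data = make_data(n=50, seed=9, q_img=6)
        basis = ISplineBasis.from_data(data.L, data.R)
        groups = [np.arange(3), np.arange(3, 6)]
        lmax = lambda_max(data, basis, 0.0, groups)
        pen = PenaltySpec(lam=lmax * 1.05, groups=groups)
        fit = fit_em(data, basis, 0.0, penalty=pen, tol=1e-5)
        assert fit.selected == []
        np.testing.assert_array_equal(fit.params.gamma, 0.0)

    def test_lambda_zero_matches_generic_optimizer(self):
        """Unpenalized gamma update agrees with scipy maximizing the same
        revised Q surface."""
        data = make_data(n=60, seed=10, q_img=2)
        basis = ISplineBasis.from_data(data.L, data.R)
        rng = np.random.default_rng(11)
        params = ModelParams(rng.uniform(0.05, 0.3, basis.J),
                             np.array([0.3, -0.2]), np.zeros(2), rho=0.0)
        rates = augmentation_rates(params, data, basis)
        mom = e_step(rates, 0.0, dL=data.is_left, dI=data.is_interval,
                     dR=data.is_right)
        prep = _Prepared(data, basis)
        ctx = _QContext(prep, mom)
        pen = PenaltySpec(lam=0.0, groups=[np.arange(2)])
        gamma = np.zeros(2)
        for _ in range(200):
            gamma = update_gamma(mom, data, basis, params.beta, gamma, pen)
        res = minimize(lambda g: -ctx.value(ctx.eta(params.beta, g)),
                       np.zeros(2), method="BFGS")
        np.testing.assert_allclose(gamma, res.x, atol=1e-4)

    def test_sweep_never_decreases_penalized_q(self):
        data = make_data(n=50, seed=12, q_img=6)
        basis = ISplineBasis.from_data(data.L, data.R)
        groups = [np.arange(3), np.arange(3, 6)]
        rng = np.random.default_rng(13)
        params = ModelParams(rng.uniform(0.05, 0.3, basis.J),
                             np.array([0.3, -0.2]), rng.normal(0, 0.2, 6),
                             rho=0.5)
        rates = augmentation_rates(params, data, basis)
        mom = e_step(rates, 0.5, dL=data.is_left, dI=data.is_interval,
                     dR=data.is_right)
        prep = _Prepared(data, basis)
        ctx = _QContext(prep, mom)
        pen = PenaltySpec(lam=2.0, groups=groups)

        def pen_q(g):
            return ctx.value(ctx.eta(params.beta, g)) - pen.lam * sum(
                pen.scale(len(ix)) * np.linalg.norm(g[ix]) for ix in groups)

        g0 = params.gamma
        g1 = update_gamma(mom, data, basis, params.beta, g0, pen)
        assert pen_q(g1) >= pen_q(g0) - 1e-10 * (1 + abs(pen_q(g0)))


class TestFitEM:
    def test_monotone_penalized_loglik(self):
        data = make_data(n=60, seed=14, q_img=6, rho=0.5)
        basis = ISplineBasis.from_data(data.L, data.R)
        pen = PenaltySpec(lam=1.0, groups=[np.arange(3), np.arange(3, 6)])
        fit = fit_em(data, basis, 0.5, penalty=pen, tol=1e-6, max_iter=300,
                     track_loglik=True)
        tr = np.array(fit.trace)
        assert (np.diff(tr) >= -1e-8 * np.maximum(1, np.abs(tr[:-1]))).all()

    def test_deterministic_rerun(self):
        data = make_data(n=40, seed=15, q_img=4)
        basis = ISplineBasis.from_data(data.L, data.R)
        pen = PenaltySpec(lam=0.5, groups=[np.arange(4)])
        f1 = fit_em(data, basis, 0.0, penalty=pen, tol=1e-5)
        f2 = fit_em(data, basis, 0.0, penalty=pen, tol=1e-5)
        np.testing.assert_array_equal(f1.params.omega, f2.params.omega)
        np.testing.assert_array_equal(f1.params.beta, f2.params.beta)
        np.testing.assert_array_equal(f1.params.gamma, f2.params.gamma)

    def test_no_signal_large_lambda_selects_nothing(self):
        rng = np.random.default_rng(16)
        data = make_data(n=80, seed=16)
        xi = rng.standard_normal((len(data), 6))  # pure-noise scores
        data = SurvivalData(data.L, data.R, data.Z, xi=xi)
        basis = ISplineBasis.from_data(data.L, data.R)
        groups = [np.arange(3), np.arange(3, 6)]
        lmax = lambda_max(data, basis, 0.0, groups)
        pen = PenaltySpec(lam=lmax, groups=groups)
        fit = fit_em(data, basis, 0.0, penalty=pen, tol=1e-4)
        assert fit.selected == []

    def test_not_converged_flagged(self):
        data = make_data(n=40, seed=17)
        basis = ISplineBasis.from_data(data.L, data.R)
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_em(data, basis, 0.0, tol=1e-14, max_iter=3)
        assert not fit.converged


class TestFitPath:
    def test_df_at_lambda_infinity_endpoint(self):
        data = make_data(n=50, seed=18, q_img=6)
        basis = ISplineBasis.from_data(data.L, data.R)
        groups = [np.arange(3), np.arange(3, 6)]
        lmax = lambda_max(data, basis, 0.0, groups)
        fits, _ = fit_path(data, basis, 0.0, [lmax * 2], groups)
        f = fits[0]
        assert f.selected == []
        assert f.df == np.count_nonzero(f.params.omega) + 2

    def test_aic_consistent_with_stored_values(self):
        data = make_data(n=50, seed=19, q_img=4)
        basis = ISplineBasis.from_data(data.L, data.R)
        groups = [np.arange(4)]
        lmax = lambda_max(data, basis, 0.0, groups)
        fits, best = fit_path(data, basis, 0.0, np.geomspace(lmax, lmax / 20, 4),
                              groups)
        for f in fits:
            assert abs(f.aic - (-2 * f.loglik + 2 * f.df)) < 1e-10
        assert best == int(np.argmin([f.aic for f in fits]))

    def test_warm_equals_cold_start(self):
        data = make_data(n=50, seed=20, q_img=4)
        basis = ISplineBasis.from_data(data.L, data.R)
        groups = [np.arange(4)]
        lmax = lambda_max(data, basis, 0.0, groups)
        grid = np.geomspace(lmax, lmax / 10, 3)
        fits_warm, _ = fit_path(data, basis, 0.0, grid, groups, tol=1e-7,
                                max_iter=3000)
        for lam, fw in zip(grid, fits_warm):
            pen = PenaltySpec(lam=float(lam), groups=groups)
            fc = fit_em(data, basis, 0.0, penalty=pen, tol=1e-7, max_iter=3000)
            np.testing.assert_allclose(fw.params.beta, fc.params.beta, atol=1e-4)
            np.testing.assert_allclose(fw.params.gamma, fc.params.gamma,
                                       atol=1e-4)


class TestParameterRecovery:
    def test_beta_recovered_without_imaging_signal(self):
        """Unpenalized Cox-case fits at n=500 recover beta = (0.5, -0.5)
        within two Monte-Carlo standard errors over replicates."""
        betas = []
        for seed in range(12):
            data = make_data(n=500, seed=300 + seed)
            basis = ISplineBasis.from_data(data.L, data.R)
            fit = fit_em(data, basis, rho=0.0, tol=1e-4, max_iter=1000)
            betas.append(fit.params.beta)
        betas = np.array(betas)
        mean = betas.mean(axis=0)
        se = betas.std(axis=0, ddof=1) / np.sqrt(len(betas))
        for j, truth in enumerate([0.5, -0.5]):
            assert abs(mean[j] - truth) < 2 * np.maximum(se[j], 1e-3)
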