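"""Semiparametric transformation model for interval-censored event times.

The conditional cumulative hazard is

    Lambda(t | X, Z) = G( Lambda(t) exp(beta'Z + gamma'xi) ; rho ),

with the logarithmic transformation G(x; rho) = log(1 + rho x) / rho
(generalized odds-rate family): rho = 0 is the Cox proportional-hazards
model and rho = 1 the proportional-odds model.  G is minus the log Laplace
transform of a gamma frailty with mean 1 and variance rho, which is what
makes the Poisson-augmented EM of :mod:`trisurv.em` possible.

The baseline Lambda is approximated by a monotone I-spline sieve
Lambda~(t) = sum_j omega_j I_j(t) with omega_j >= 0, the I_j built on
[0, tmax] with tmax the largest finite interval endpoint.

Event times are observed as intervals (L, R]: L = 0 with finite R for
left-censored subjects, R = inf for right-censored ones, 0 < L < R < inf
for interval-censored ones.  The censoring class is always inferred from
(L, R), never from user flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline


# -- transformation and frailty Laplace transform --------------------------

def transform_G(x, rho: float, deriv: bool = False):
    """Logarithmic transformation G(x; rho) = log(1 + rho x)/rho, G(x; 0) = x.

    With ``deriv=True`` also returns dG/dx = 1/(1 + rho x).
    """
    x = np.asarray(x, dtype=float)
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    if np.any(x < 0):
        raise ValueError("G is defined for x >= 0")
    if rho == 0:
        g = x.copy()
    else:
        g = np.log1p(rho * x) / rho
    if deriv:
        return g, 1.0 / (1.0 + rho * x)
    return g


def laplace_phi(x, rho: float, deriv: bool = False):
    """Gamma-frailty Laplace transform Phi(x; rho) = exp(-G(x; rho)).

    Phi(x) = (1 + rho x)^(-1/rho) for rho > 0 and exp(-x) at rho = 0; with
    ``deriv=True`` also returns nu(x) = -Phi'(x) = (1 + rho x)^(-1/rho - 1).
    """
    x = np.asarray(x, dtype=float)
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    if np.any(x < 0):
        raise ValueError("Phi is defined for x >= 0")
    if rho == 0:
        phi = np.exp(-x)
        nu = phi
    else:
        phi = np.exp(-np.log1p(rho * x) / rho)
        nu = np.exp(-(1.0 / rho + 1.0) * np.log1p(rho * x))
    return (phi, nu) if deriv else phi


# -- I-spline sieve --------------------------------------------------------

@dataclass
class ISplineBasis:
    """Monotone I-spline basis on [0, tmax].

    Degree-k I-splines are antiderivatives of degree-(k-1) M-splines; with
    ``n_interior`` interior knots there are J = degree + n_interior basis
    functions, each nondecreasing with I_j(0) = 0 and I_j(tmax) = 1, so any
    nonnegative combination is a valid baseline cumulative hazard.
    """

    interior_knots: np.ndarray
    tmax: float
    degree: int = 3
    _splines: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        self.interior_knots = np.sort(np.asarray(self.interior_knots, dtype=float))
        k = self.degree
        t = np.r_[np.zeros(k), self.interior_knots, np.full(k, self.tmax)]
        J = len(t) - k
        self._splines = []
        for j in range(J):
            c = np.zeros(J)
            c[j] = 1.0
            b = BSpline(t, c, k - 1, extrapolate=False)
            anti = b.antiderivative()
            # M-spline normalization: the B-spline integrates to (t[j+k]-t[j])/k
            span = t[j + k] - t[j]
            scale = k / span if span > 0 else 0.0
            self._splines.append((anti, scale))

    @property
    def J(self) -> int:
        return len(self._splines)

    @classmethod
    def from_data(cls, L, R, degree: int = 3, n_interior: int = 4) -> "ISplineBasis":
        """Knots at the j/(n_interior+1) empirical quantiles (j = 1..n_interior)
        of the pooled finite positive endpoints {L > 0} U {R < inf}; tmax is
        the largest finite endpoint."""
        L = np.asarray(L, dtype=float)
        R = np.asarray(R, dtype=float)
        pooled = np.concatenate([L[L > 0], R[np.isfinite(R)]])
        if pooled.size == 0:
            raise ValueError("no finite positive endpoints to place knots")
        tmax = float(pooled.max())
        q = np.arange(1, n_interior + 1) / (n_interior + 1)
        knots = np.quantile(pooled, q)
        knots = np.clip(knots, 1e-8 * tmax, tmax * (1 - 1e-8))
        return cls(interior_knots=knots, tmax=tmax, degree=degree)

    def design(self, times) -> np.ndarray:
        """Matrix of I_j(t); t < 0 errors, t > tmax is clamped with a warning."""
        t = np.asarray(times, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if np.any(t > self.tmax * (1 + 1e-12)):
            warnings.warn("times beyond tmax clamped to tmax")
        tc = np.minimum(t, self.tmax)
        out = np.empty(tc.shape + (self.J,))
        for j, (anti, scale) in enumerate(self._splines):
            v = anti(tc) * scale
            out[..., j] = np.nan_to_num(v, nan=0.0)
        return np.clip(out, 0.0, 1.0)

    def cumhaz(self, omega, times) -> np.ndarray:
        return self.design(times) @ np.asarray(omega, dtype=float)


# -- data container --------------------------------------------------------

@dataclass
class SurvivalData:
    """Interval-censored survival records with covariates.

    ``L``/``R`` are (n,) with R = np.inf allowed; ``Z`` (n, p) unpenalized
    covariates; ``xi`` (n, q) imaging scores or None.  Censoring classes are
    derived: left iff L == 0 and R finite, right iff R == inf, interval
    otherwise.
    """

    L: np.ndarray
    R: np.ndarray
    Z: np.ndarray
    xi: np.ndarray | None = None

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] != len(self.L):
            self.Z = self.Z.T
        if self.xi is not None:
            self.xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        if np.any(self.L < 0) or np.any(self.R <= self.L):
            raise ValueError("need 0 <= L < R for every record")

    def __len__(self) -> int:
        return len(self.L)

    @property
    def is_left(self) -> np.ndarray:
        return (self.L == 0) & np.isfinite(self.R)

    @property
    def is_right(self) -> np.ndarray:
        return ~np.isfinite(self.R)

    @property
    def is_interval(self) -> np.ndarray:
        return ~self.is_left & ~self.is_right

    @property
    def covariates(self) -> np.ndarray:
        if self.xi is None:
            return self.Z
        return np.hstack([self.Z, self.xi])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": np.arange(len(self)), "L": self.L, "R": self.R})
        for j in range(self.Z.shape[1]):
            df[f"Z{j + 1}"] = self.Z[:, j]
        return df

    def to_file(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_file(cls, path, xi=None) -> "SurvivalData":
        df = pd.read_csv(path, float_precision="round_trip")
        zcols = [c for c in df.columns if c.startswith("Z")]
        return cls(df["L"].to_numpy(), df["R"].to_numpy(),
                   df[zcols].to_numpy(), xi=xi)


@dataclass
class ModelParams:
    """theta = (omega, beta, gamma) at fixed transformation parameter rho."""

    omega: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray | None
    rho: float

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.omega < 0):
            raise ValueError("omega must be elementwise nonnegative")

    def linear_predictor(self, Z, xi=None) -> np.ndarray:
        eta = np.atleast_2d(Z) @ self.beta
        if self.gamma is not None and xi is not None:
            eta = eta + np.atleast_2d(xi) @ self.gamma
        return eta


# -- likelihood and survival function --------------------------------------

def _log_survival_terms(params: ModelParams, data: SurvivalData,
                        basis: ISplineBasis):
    """log exp-terms at L and R: returns (-G(Lam(L) e^eta), -G(Lam(R) e^eta))
    with the R-term = -inf marker for right-censored subjects."""
    eta = params.linear_predictor(data.Z, data.xi)
    e = np.exp(eta)
    lamL = np.where(data.L > 0, basis.cumhaz(params.omega, np.minimum(data.L, basis.tmax)), 0.0)
    Rfin = np.isfinite(data.R)
    lamR = np.zeros(len(data))
    if Rfin.any():
        lamR[Rfin] = basis.cumhaz(params.omega, np.minimum(data.R[Rfin], basis.tmax))
    gL = transform_G(lamL * e, params.rho)
    gR = np.full(len(data), np.inf)
    gR[Rfin] = transform_G(lamR[Rfin] * e[Rfin], params.rho)
    return gL, gR


def observed_loglik(params: ModelParams, data: SurvivalData,
                    basis: ISplineBasis) -> float:
    """Observed-data log-likelihood sum_i log[exp(-G_L) - exp(-G_R)].

    Uses exp(-G(0)) = 1 for left-censored subjects and a zero R-term for
    right-censored ones.  Returns -inf (with a warning naming the records)
    if an interval record has Lambda~(R) <= Lambda~(L) numerically.
    """
    gL, gR = _log_survival_terms(params, data, basis)
    out = np.empty(len(data))
    right = ~np.isfinite(gR)
    out[right] = -gL[right]
    fin = ~right
    diff = gR[fin] - gL[fin]
    if np.any(diff <= 0):
        bad = np.nonzero(fin)[0][diff <= 0]
        warnings.warn(f"nonpositive likelihood contribution for records {bad.tolist()}")
        return -np.inf
    # log(e^{-gL} - e^{-gR}) = -gL + log1p(-e^{-(gR-gL)})
    out[fin] = -gL[fin] + np.log1p(-np.exp(-diff))
    return float(out.sum())


def survival_prob(params: ModelParams, basis: ISplineBasis, t, Z, xi=None) -> np.ndarray:
    """S(t | Z, xi) = exp(-G(Lambda~(t) e^eta; rho)) for scalar or vector t."""
    t = np.asarray(t, dtype=float)
    eta = float(params.linear_predictor(np.atleast_2d(Z),
                                        None if xi is None else np.atleast_2d(xi))[0])
    lam = basis.cumhaz(params.omega, np.minimum(t, basis.tmax))
    return np.exp(-transform_G(lam * np.exp(eta), params.rho))
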