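"""First-stage image smoothing and score construction.

Each subject's image, observed as noisy samples Y_ij = X_i(s_ij) + eps_ij at
scattered locations inside the domain, is fitted by a bivariate spline:
minimize ||Y - D alpha||^2 + varsigma * alpha' P alpha subject to the
cross-edge smoothness constraint H alpha = 0, where D is the Bernstein
design matrix, P the thin-plate energy matrix and varsigma >= 0 a roughness
penalty.  The constraint is removed by reparameterizing alpha = N c with the
columns of N an orthonormal basis of ker(H), leaving a single symmetric
positive-definite solve.

The fitted coefficient vectors are reduced to imaging covariates through
xi_i = W alpha_i (W the block-diagonal Gram matrix), so that for any spline
coefficient vector g, g' xi_i equals the L2 inner product of the two spline
surfaces over the domain.  For estimation each coordinate of xi is z-scored
across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


def null_space_basis(H, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of ker(H) via SVD with a relative rank tolerance."""
    if sp.issparse(H):
        H = H.toarray()
    H = np.asarray(H, dtype=float)
    if H.shape[0] == 0:
        return np.eye(H.shape[1])
    _, s, Vt = np.linalg.svd(H, full_matrices=True)
    rank = int(np.sum(s > rtol * s[0])) if len(s) else 0
    return Vt[rank:].T


class SurfaceSmoother:
    """Penalized constrained least-squares smoother at fixed sample points.

    Pre-factors everything that does not depend on the data, so that many
    subjects observed at the same pixel locations can be fitted in one
    batched solve.
    """

    def __init__(self, system, points, H=None, P=None, r: int = 1):
        self.system = system
        if H is None:
            H = system.smoothness_matrix(r) if system.degree > r else sp.csr_matrix(
                (0, system.n_coef))
        if P is None:
            P = system.energy_matrix()
        self.D = system.build_design(points)
        self.N = null_space_basis(H)
        if self.N.shape[1] == 0:
            raise ValueError("smoothness constraint leaves no free parameters")
        self.DN = np.asarray(self.D @ self.N)            # (n_pts, m)
        self.G = self.DN.T @ self.DN                     # reduced normal matrix
        self.Pn = self.N.T @ (P @ self.N)
        self.n_points = self.DN.shape[0]

    def fit(self, Y, varsigma: float):
        """Return alpha-hat for one image (n_pts,) or a batch (n_subj, n_pts)."""
        if varsigma < 0:
            raise ValueError("varsigma must be nonnegative")
        Y = np.asarray(Y, dtype=float)
        single = Y.ndim == 1
        rhs = self.DN.T @ np.atleast_2d(Y).T             # (m, n_subj)
        A = self.G + varsigma * self.Pn
        try:
            c = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular reduced normal equations; increase varsigma or "
                "coarsen the mesh") from exc
        alpha = (self.N @ c).T                           # (n_subj, MK)
        return alpha[0] if single else alpha

    def fitted_values(self, alpha):
        return np.asarray(self.D @ np.atleast_2d(alpha).T).T.squeeze()

    def gcv(self, Y, grid) -> float:
        """Generalized cross-validation choice of varsigma over a grid."""
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0 or np.any(grid < 0):
            raise ValueError("need a nonempty grid of nonnegative varsigma")
        if grid.size == 1:
            return float(grid[0])
        Y = np.asarray(Y, dtype=float).ravel()
        n = self.n_points
        rhs = self.DN.T @ Y
        best, best_score = float(grid[0]), np.inf
        for vs in grid:
            A = self.G + vs * self.Pn
            try:
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                continue
            c = Ainv @ rhs
            fitted = self.DN @ c
            rss = float(np.sum((Y - fitted) ** 2))
            edf = float(np.trace(self.G @ Ainv))
            denom = max(n - edf, 1e-8)
            score = n * rss / denom ** 2
            if score < best_score * (1 - 1e-12):
                best, best_score = float(vs), score
        return best


def fit_surface(Y, system, points, H=None, P=None, varsigma: float = 0.0, r: int = 1):
    """One-off constrained penalized fit; see :class:`SurfaceSmoother`."""
    return SurfaceSmoother(system, points, H=H, P=P, r=r).fit(Y, varsigma)


def select_roughness(Y, system, points, grid, H=None, P=None, r: int = 1) -> float:
    return SurfaceSmoother(system, points, H=H, P=P, r=r).gcv(Y, grid)


@dataclass
class ImageScores:
    """Per-subject spline coefficients and (optionally standardized) scores."""

    alpha: np.ndarray          # (n, MK)
    xi: np.ndarray             # (n, MK), standardized when center is not None
    center: np.ndarray | None  # per-coordinate standardization parameters
    scale: np.ndarray | None

    @property
    def xi_raw(self) -> np.ndarray:
        if self.center is None:
            return self.xi
        return self.xi * self.scale + self.center

    def standardize_new(self, xi_new: np.ndarray) -> np.ndarray:
        """Apply the stored standardization to raw scores of new subjects."""
        if self.center is None:
            return np.asarray(xi_new)
        return (np.asarray(xi_new) - self.center) / self.scale


def compute_scores(alphas, gram, standardize: bool = True) -> ImageScores:
    """Scores xi_i = W alpha_i, optionally z-scored per coordinate.

    ``gram`` is the global block-diagonal W (sparse or dense).  Coordinates
    with zero variance across subjects are left at zero rather than divided
    by zero.
    """
    alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
    if gram.shape[1] != alphas.shape[1]:
        raise ValueError("alpha length does not match the Gram matrix")
    xi = np.asarray((gram @ alphas.T).T)
    if not standardize:
        return ImageScores(alphas, xi, None, None)
    center = xi.mean(axis=0)
    scale = xi.std(axis=0, ddof=0)
    ok = scale > 1e-12
    safe = np.where(ok, scale, 1.0)
    z = np.where(ok, (xi - center) / safe, 0.0)
    return ImageScores(alphas, z, center, safe)
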