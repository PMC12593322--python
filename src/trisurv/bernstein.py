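"""Bernstein-Bezier polynomial systems on a triangulation.

On each triangle tau with barycentric coordinates (b1, b2, b3) the degree-d
Bernstein basis is

    B_ijk(s) = d!/(i! j! k!) b1^i b2^j b3^k,     i + j + k = d,

giving K = (d+2)(d+1)/2 functions per triangle that are nonnegative inside
tau and sum to one.  A spline is a stacked coefficient vector alpha of
length M*K; cross-edge smoothness of order r is imposed linearly as
H alpha = 0.  The module provides exact (closed-form) Gram and thin-plate
energy matrices, built from the monomial integral

    integral_tau b1^a b2^b b3^c dA = 2 area(tau) a! b! c! / (a+b+c+2)!.

Multi-indices (i, j, k) are ordered lexicographically decreasing, e.g. for
d=2: (2,0,0), (1,1,0), (1,0,1), (0,2,0), (0,1,1), (0,0,2); the same ordering
is used consistently by the design, Gram, energy and smoothness matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import scipy.sparse as sp

from .triangulation import Triangulation, barycentric_coords


def multi_indices(d: int) -> list[tuple[int, int, int]]:
    """Degree-d triangular multi-indices in decreasing lexicographic order."""
    return [(i, j, d - i - j) for i in range(d, -1, -1) for j in range(d - i, -1, -1)]


def _bb_monomial_integral(a: int, b: int, c: int, area: float) -> float:
    return 2.0 * area * factorial(a) * factorial(b) * factorial(c) / factorial(a + b + c + 2)


@dataclass
class BernsteinSystem:
    """Degree-d Bernstein basis over every triangle of a mesh."""

    mesh: Triangulation
    degree: int

    def __post_init__(self):
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")
        self.indices = multi_indices(self.degree)
        self.K = len(self.indices)
        assert self.K == (self.degree + 2) * (self.degree + 1) // 2
        self._mult = np.array(
            [factorial(self.degree) / (factorial(i) * factorial(j) * factorial(k))
             for i, j, k in self.indices])
        self._pow = np.array(self.indices)  # (K, 3)

    @property
    def n_coef(self) -> int:
        """Total length of the stacked coefficient vector alpha (M*K)."""
        return self.mesh.n_triangles * self.K

    # -- evaluation --------------------------------------------------------

    def eval_bary(self, bary) -> np.ndarray:
        """Basis values at barycentric coordinates ``bary`` ((3,) or (n,3))."""
        b = np.atleast_2d(np.asarray(bary, dtype=float))
        with np.errstate(invalid="ignore"):
            vals = self._mult * np.prod(b[:, None, :] ** self._pow[None, :, :], axis=2)
        return vals[0] if np.asarray(bary).ndim == 1 else vals

    def eval_bernstein(self, tri_index: int, p, extrapolate: bool = False) -> np.ndarray:
        """The K basis values of triangle ``tri_index`` at Cartesian point p."""
        b = barycentric_coords(self.mesh.triangle_vertices(tri_index), p)
        if not extrapolate and np.any(np.atleast_2d(b) < -1e-9):
            raise ValueError("point outside triangle; pass extrapolate=True to override")
        return self.eval_bary(b)

    def build_design(self, points, on_outside: str = "error"):
        """Sparse design matrix D mapping alpha to spline values at ``points``.

        Row i has at most K nonzeros, in the column block of the triangle
        containing point i (ties on shared edges go to the lowest triangle
        index).  Points outside the mesh raise an error listing their
        indices, or are dropped when ``on_outside='drop'`` (the kept row
        indices are then returned alongside the matrix).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tri_idx, bary = self.mesh.locate(points)
        outside = np.nonzero(tri_idx < 0)[0]
        if len(outside):
            if on_outside == "error":
                raise ValueError(f"points outside the domain at indices {outside.tolist()}")
            keep = tri_idx >= 0
            points, tri_idx, bary = points[keep], tri_idx[keep], bary[keep]
        vals = self.eval_bary(np.clip(bary, 0.0, None))
        n = len(points)
        rows = np.repeat(np.arange(n), self.K)
        cols = (tri_idx[:, None] * self.K + np.arange(self.K)[None, :]).ravel()
        D = sp.csr_matrix((vals.ravel(), (rows, cols)), shape=(n, self.n_coef))
        if on_outside == "drop" and len(outside):
            return D, np.nonzero(tri_idx >= 0)[0]
        return D

    # -- Gram (the W matrix) ----------------------------------------------

    def triangle_gram(self, tri_index: int) -> np.ndarray:
        """Exact K x K Gram matrix W_tau = <B_tau, B_tau^T> on one triangle."""
        area = self.mesh.areas[tri_index]
        K = self.K
        W = np.empty((K, K))
        for p in range(K):
            for q in range(p, K):
                a = self._pow[p] + self._pow[q]
                W[p, q] = W[q, p] = (self._mult[p] * self._mult[q]
                                    * _bb_monomial_integral(a[0], a[1], a[2], area))
        return W

    def gram_blocks(self) -> list[np.ndarray]:
        return [self.triangle_gram(l) for l in range(self.mesh.n_triangles)]

    def gram_matrix(self):
        """Global block-diagonal W (sparse)."""
        return sp.block_diag(self.gram_blocks(), format="csr")

    # -- thin-plate energy -------------------------------------------------

    def _bary_gradients(self, tri_index: int) -> np.ndarray:
        """(3, 2) Cartesian gradients of (b1, b2, b3); constant per triangle."""
        v = self.mesh.triangle_vertices(tri_index)
        ones = np.column_stack([np.ones(3), v])
        # b(x) = A^{-1} [1, x, y]; gradient rows are columns 1:3 of A^{-1}
        Ainv = np.linalg.inv(ones.T)
        return Ainv[:, 1:]

    def _second_derivative_polys(self, tri_index: int):
        """For each basis function, the three second derivatives (xx, xy, yy)
        as barycentric-monomial dictionaries of degree d-2."""
        g = self._bary_gradients(tri_index)  # (3,2)
        d = self.degree
        out = []
        for p in range(self.K):
            poly = {tuple(self._pow[p]): self._mult[p]}
            dx = _bary_diff(poly, g[:, 0])
            dy = _bary_diff(poly, g[:, 1])
            out.append((_bary_diff(dx, g[:, 0]),
                        _bary_diff(dx, g[:, 1]),
                        _bary_diff(dy, g[:, 1])))
        assert all(all(sum(m) == d - 2 for m in t) for trip in out for t in trip) or d < 2
        return out

    def triangle_energy(self, tri_index: int) -> np.ndarray:
        """Exact K x K matrix of integral(u_xx v_xx + 2 u_xy v_xy + u_yy v_yy)."""
        K = self.K
        if self.degree < 2:
            return np.zeros((K, K))
        area = self.mesh.areas[tri_index]
        polys = self._second_derivative_polys(tri_index)
        P = np.empty((K, K))
        for p in range(K):
            for q in range(p, K):
                tot = 0.0
                for w, a, b in ((1.0, 0, 0), (2.0, 1, 1), (1.0, 2, 2)):
                    tot += w * _poly_product_integral(polys[p][a], polys[q][b], area)
                P[p, q] = P[q, p] = tot
        return P

    def energy_matrix(self):
        """Global block-diagonal thin-plate energy matrix P (sparse, PSD).

        Zero (with no curvature to penalize) when degree < 2.
        """
        if self.degree < 2:
            import warnings
            warnings.warn("degree < 2: thin-plate energy is identically zero")
            return sp.csr_matrix((self.n_coef, self.n_coef))
        return sp.block_diag(
            [self.triangle_energy(l) for l in range(self.mesh.n_triangles)],
            format="csr")

    # -- smoothness constraints -------------------------------------------

    def smoothness_matrix(self, r: int = 1) -> sp.csr_matrix:
        """Constraint matrix H with H alpha = 0 iff the spline is C^r across
        every interior edge (0 <= r < degree required).

        For triangles T (lower index) and T~ sharing edge e, the C^m
        condition determines each T~ coefficient whose off-edge index equals
        m from a degree-m de Casteljau combination of T's coefficients at
        the barycentric coordinates (w.r.t. T) of T~'s off-edge vertex.
        """
        d = self.degree
        if r < 0 or r >= d:
            raise ValueError(f"smoothness order r={r} requires 0 <= r < degree ({d})")
        pos = {idx: m for m, idx in enumerate(self.indices)}
        rows, cols, vals = [], [], []
        nrow = 0
        for (va, vb, l1, l2) in self.mesh.interior_edges():
            t1 = self.mesh.triangles[l1]
            t2 = self.mesh.triangles[l2]
            # local vertex slots of the shared edge in each triangle
            q1, r1 = (list(t1).index(va), list(t1).index(vb))
            q2, r2 = (list(t2).index(va), list(t2).index(vb))
            p2 = ({0, 1, 2} - {q2, r2}).pop()  # off-edge slot of T~
            lam = barycentric_coords(self.mesh.triangle_vertices(l1),
                                     self.mesh.triangle_vertices(l2)[p2])
            for m in range(r + 1):
                for j in range(d - m + 1):
                    k = d - m - j
                    # T~ coefficient with p2-index m, q2-index j, r2-index k
                    idx2 = [0, 0, 0]
                    idx2[p2], idx2[q2], idx2[r2] = m, j, k
                    rows.append(nrow)
                    cols.append(l2 * self.K + pos[tuple(idx2)])
                    vals.append(-1.0)
                    for mu in multi_indices(m):
                        coef = (factorial(m) / (factorial(mu[0]) * factorial(mu[1])
                                                * factorial(mu[2]))
                                * lam[0] ** mu[0] * lam[1] ** mu[1] * lam[2] ** mu[2])
                        idx1 = list(mu)
                        idx1[q1] += j
                        idx1[r1] += k
                        rows.append(nrow)
                        cols.append(l1 * self.K + pos[tuple(idx1)])
                        vals.append(coef)
                    nrow += 1
        H = sp.csr_matrix((vals, (rows, cols)), shape=(nrow, self.n_coef))
        return H


def _bary_diff(poly: dict, gdir: np.ndarray) -> dict:
    """Directional Cartesian derivative of a barycentric-monomial polynomial.

    ``poly`` maps (a, b, c) -> coefficient; ``gdir`` holds d b_t / d x (or
    / d y) for t = 1, 2, 3.
    """
    out: dict = {}
    for (a, b, c), coef in poly.items():
        for t, e in enumerate(((1, 0, 0), (0, 1, 0), (0, 0, 1))):
            m = (a, b, c)[t]
            if m == 0 or gdir[t] == 0.0:
                continue
            key = (a - e[0], b - e[1], c - e[2])
            out[key] = out.get(key, 0.0) + coef * m * gdir[t]
    return out


def _poly_product_integral(p1: dict, p2: dict, area: float) -> float:
    tot = 0.0
    for m1, c1 in p1.items():
        for m2, c2 in p2.items():
            tot += c1 * c2 * _bb_monomial_integral(m1[0] + m2[0], m1[1] + m2[1],
                                                   m1[2] + m2[2], area)
    return tot
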