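import numpy as np
import pytest

from trisurv.bernstein import BernsteinSystem
from trisurv.triangulation import Triangulation


@pytest.fixture
def square_mesh():
    """Unit square split into two triangles along the diagonal."""
    return Triangulation(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]),
                         np.array([[0, 1, 2], [0, 2, 3]]))


@pytest.fixture
def unit_triangle_mesh():
    return Triangulation(np.array([[0.0, 0], [1, 0], [0, 1]]),
                         np.array([[0, 1, 2]]))


def random_mesh(n_extra: int, seed: int) -> Triangulation:
    """Small conforming mesh: Delaunay of the unit-square corners plus
    ``n_extra`` interior points."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    pts = np.vstack([[[0, 0], [1, 0], [1, 1], [0, 1]],
                     rng.uniform(0.15, 0.85, size=(n_extra, 2))])
    dt = Delaunay(pts)
    return Triangulation(pts, dt.simplices)


def interpolate_polynomial(system: BernsteinSystem, f) -> np.ndarray:
    """Exact per-triangle Bernstein coefficients of a bivariate polynomial of
    degree <= d, by interpolation at the domain points of each triangle."""
    from trisurv.triangulation import barycentric_coords

    d = system.degree
    alpha = np.zeros(system.n_coef)
    for l in range(system.mesh.n_triangles):
        V = system.mesh.triangle_vertices(l)
        P = np.array([(i * V[0] + j * V[1] + k * V[2]) / d
                      for (i, j, k) in system.indices])
        B = np.array([system.eval_bary(barycentric_coords(V, p)) for p in P])
        y = np.array([f(*p) for p in P])
        alpha[l * system.K:(l + 1) * system.K] = np.linalg.solve(B, y)
    return alpha


def triangle_quadrature(f, V, n: int = 12):
    """Gauss-Legendre quadrature on a triangle via the Duffy transform;
    exact for polynomials of degree <= 2n-3.  Oracle use only."""
    x, w = np.polynomial.legendre.leggauss(n)
    u = 0.5 * (x + 1)
    wu = 0.5 * w
    A2 = abs((V[1, 0] - V[0, 0]) * (V[2, 1] - V[0, 1])
             - (V[1, 1] - V[0, 1]) * (V[2, 0] - V[0, 0]))
    tot = 0.0
    for a, wa in zip(u, wu):
        for b, wb in zip(u, wu):
            b1 = a
            b2 = b * (1 - a)
            p = b1 * V[0] + b2 * V[1] + (1 - b1 - b2) * V[2]
            tot += wa * wb * (1 - a) * f(p)
    return tot * A2
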