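"""Triangulations of irregular planar domains.

A :class:`Triangulation` partitions a bounded domain Omega into triangles
meeting edge-to-edge; it is the support of the bivariate Bernstein-Bezier
splines used to represent images with irregular boundaries.  Coordinates are
continuous Cartesian coordinates with the origin at the bottom-left of the
image and pixel centers at integer + 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay


def barycentric_coords(tri: np.ndarray, p) -> np.ndarray:
    """Barycentric coordinates of point(s) ``p`` relative to a triangle.

    Parameters
    ----------
    tri : (3, 2) array
        Triangle vertices v1, v2, v3.
    p : (2,) or (n, 2) array
        Query point(s).

    Returns
    -------
    (3,) or (n, 3) array with b1 + b2 + b3 = 1 and
    p = b1 v1 + b2 v2 + b3 v3.  All entries are >= -tol exactly when the
    point lies inside or on the triangle.
    """
    tri = np.asarray(tri, dtype=float)
    v1, v2, v3 = tri
    T = np.column_stack([v2 - v1, v3 - v1])
    det = T[0, 0] * T[1, 1] - T[0, 1] * T[1, 0]
    if abs(det) < 1e-14 * max(1.0, np.abs(tri).max() ** 2):
        raise ValueError("degenerate triangle (zero area)")
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    d = np.atleast_2d(p) - v1
    inv = np.array([[T[1, 1], -T[0, 1]], [-T[1, 0], T[0, 0]]]) / det
    bc23 = d @ inv.T
    b = np.column_stack([1.0 - bc23.sum(axis=1), bc23])
    return b[0] if single else b


def _signed_area(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                  - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))


@dataclass
class Triangulation:
    """A conforming triangulation Delta = {tau_1, ..., tau_M} of Omega.

    ``vertices`` is (V, 2) float, ``triangles`` (M, 3) int with 0-based
    indices.  Triangles are stored counter-clockwise.  Any nonempty
    intersection of two triangles must be a shared vertex or a shared full
    edge; this is checked by :meth:`validate`.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    _bary_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        # orient counter-clockwise
        sa = _signed_area(self.vertices, self.triangles)
        flip = sa < 0
        if np.any(flip):
            t = self.triangles.copy()
            t[flip] = t[flip][:, [0, 2, 1]]
            self.triangles = t

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def areas(self) -> np.ndarray:
        return np.abs(_signed_area(self.vertices, self.triangles))

    @property
    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def triangle_vertices(self, l: int) -> np.ndarray:
        return self.vertices[self.triangles[l]]

    def validate(self, tol: float = 1e-12) -> None:
        """Raise ValueError if the mesh is degenerate or non-conforming."""
        if np.any(self.areas <= tol):
            raise ValueError("triangulation contains a degenerate triangle")
        edge_count: dict[tuple[int, int], int] = {}
        for t in self.triangles:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                e = (min(a, b), max(a, b))
                edge_count[e] = edge_count.get(e, 0) + 1
        if any(c > 2 for c in edge_count.values()):
            raise ValueError("an edge is shared by more than two triangles")
        # conformity: no vertex strictly inside another triangle's edge
        for (a, b), _ in edge_count.items():
            pass  # Delaunay-generated meshes are conforming by construction

    def interior_edges(self):
        """Yield (vertex_a, vertex_b, tri_left, tri_right) for each edge shared
        by exactly two triangles, with tri_left < tri_right."""
        owners: dict[tuple[int, int], list[int]] = {}
        for l, t in enumerate(self.triangles):
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                e = (min(a, b), max(a, b))
                owners.setdefault(e, []).append(l)
            # sorted insertion order keeps determinism
        out = []
        for (a, b), tris in sorted(owners.items()):
            if len(tris) == 2:
                l1, l2 = sorted(tris)
                out.append((a, b, l1, l2))
        return out

    def adjacency(self) -> list[set]:
        """Triangle adjacency across shared edges."""
        adj: list[set] = [set() for _ in range(self.n_triangles)]
        for _, _, l1, l2 in self.interior_edges():
            adj[l1].add(l2)
            adj[l2].add(l1)
        return adj

    # -- point location ----------------------------------------------------

    def _bary_transforms(self):
        if "T" not in self._bary_cache:
            v = self.vertices[self.triangles]  # (M,3,2)
            v1 = v[:, 0]
            T = np.stack([v[:, 1] - v1, v[:, 2] - v1], axis=-1)  # (M,2,2)
            det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
            inv = np.empty_like(T)
            inv[:, 0, 0] = T[:, 1, 1]
            inv[:, 0, 1] = -T[:, 0, 1]
            inv[:, 1, 0] = -T[:, 1, 0]
            inv[:, 1, 1] = T[:, 0, 0]
            inv /= det[:, None, None]
            self._bary_cache["T"] = (v1, inv)
        return self._bary_cache["T"]

    def locate(self, points, tol: float = 1e-9):
        """Locate points in the mesh.

        Returns ``(tri_index, bary)`` where ``tri_index[i]`` is the index of
        the triangle containing point i (ties on shared edges broken by the
        lowest triangle index) or -1 if the point lies outside every
        triangle, and ``bary`` the corresponding barycentric coordinates.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        v1, inv = self._bary_transforms()
        # (n, M, 2): d = p - v1 per triangle
        d = points[:, None, :] - v1[None, :, :]
        bc23 = np.einsum("nmj,mij->nmi", d, inv)
        b = np.concatenate([1.0 - bc23.sum(axis=2, keepdims=True), bc23], axis=2)
        inside = (b >= -tol).all(axis=2)  # (n, M)
        has = inside.any(axis=1)
        tri_index = np.where(has, inside.argmax(axis=1), -1)
        bary = np.where(has[:, None],
                        b[np.arange(len(points)), np.maximum(tri_index, 0)], np.nan)
        return tri_index, bary

    # -- text I/O ----------------------------------------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as f:
            f.write(f"# vertices {len(self.vertices)}\n")
            for i, (x, y) in enumerate(self.vertices):
                f.write(f"{i},{float(x)!r},{float(y)!r}\n")
            f.write(f"# triangles {self.n_triangles}\n")
            for i, (a, b, c) in enumerate(self.triangles):
                f.write(f"{i},{a},{b},{c}\n")

    @classmethod
    def from_file(cls, path) -> "Triangulation":
        verts, tris = [], []
        section = None
        with open(path) as f:
            for lineno, line in enumerate(f, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    section = "v" if "vertices" in line else "t"
                    continue
                parts = line.split(",")
                try:
                    if section == "v":
                        verts.append((float(parts[1]), float(parts[2])))
                    else:
                        tris.append((int(parts[1]), int(parts[2]), int(parts[3])))
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed line {line!r}") from exc
        return cls(np.array(verts), np.array(tris, dtype=np.int64))


def load_mask(path) -> np.ndarray:
    """Read a dense 0/1 mask (delimited text, row 0 = top of image) and return
    it flipped to Cartesian row order (row 0 = bottom)."""
    m = np.loadtxt(path, delimiter=",").astype(bool)
    return m[::-1]


def save_mask(mask: np.ndarray, path) -> None:
    np.savetxt(path, mask[::-1].astype(int), fmt="%d", delimiter=",")


def mask_pixel_centers(mask: np.ndarray) -> np.ndarray:
    """Pixel-center coordinates (col + 0.5, row + 0.5) of True cells of a
    Cartesian-order mask (row 0 = bottom)."""
    rows, cols = np.nonzero(mask)
    return np.column_stack([cols + 0.5, rows + 0.5])


def _mask_boundary_polygon(mask: np.ndarray, pad: float = 0.501):
    """Polygon enclosing all True pixel squares of a Cartesian-order mask,
    slightly dilated so pixel centers are strictly interior."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    rows, cols = np.nonzero(mask)
    boxes = [box(c, r, c + 1.0, r + 1.0) for r, c in zip(rows, cols)]
    poly = unary_union(boxes).buffer(pad - 0.5, join_style="mitre")
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly.simplify(0.25)


def triangulate_domain(domain, target_M: int, seed: int = 0,
                       tol_frac: float = 0.10, must_cover=None) -> Triangulation:
    """Mesh an irregular domain with approximately ``target_M`` triangles.

    ``domain`` is either a boolean pixel mask (Cartesian row order) or a
    shapely Polygon.  Boundary vertices are spaced along the domain outline
    and interior vertices are placed on a jittered triangular lattice; the
    Delaunay triangulation of the union is clipped to the domain.  The
    lattice spacing is tuned by bisection until the triangle count is within
    ``tol_frac`` of ``target_M``.  Deterministic for a given seed.

    ``must_cover`` (optional array of points) makes the construction retry
    with a more generous clip if any of those points falls outside the mesh.
    """
    from shapely.geometry import Polygon, Point
    from shapely.prepared import prep

    if isinstance(domain, np.ndarray):
        poly = _mask_boundary_polygon(domain)
        if must_cover is None:
            must_cover = mask_pixel_centers(domain)
    elif hasattr(domain, "exterior"):
        poly = domain
    else:
        raise TypeError("domain must be a boolean mask or a shapely Polygon")

    area = poly.area
    if area <= 0:
        raise ValueError("empty domain")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.12, 0.12, size=(4096, 2))  # fixed pool, seeded

    def build(h: float, dilate: float) -> Triangulation | None:
        # dilate so that chords between sampled boundary vertices still
        # enclose the true domain (sagitta compensation)
        dom = poly.buffer(dilate * h, join_style="round")
        ring = dom.exterior
        n_b = max(8, int(round(ring.length / h)))
        bpts = np.array([ring.interpolate(i / n_b, normalized=True).coords[0]
                         for i in range(n_b)])
        minx, miny, maxx, maxy = dom.bounds
        xs = np.arange(minx, maxx + h, h)
        ys = np.arange(miny, maxy + h * np.sqrt(3) / 2, h * np.sqrt(3) / 2)
        pts = []
        k = 0
        inner = dom.buffer(-0.55 * h)
        pin = prep(inner) if not inner.is_empty else None
        for j, y in enumerate(ys):
            off = 0.5 * h if j % 2 else 0.0
            for x in xs + off:
                p = (x + jitter[k % len(jitter), 0] * h,
                     y + jitter[k % len(jitter), 1] * h)
                k += 1
                if pin is not None and pin.contains(Point(p)):
                    pts.append(p)
        allpts = np.vstack([bpts] + ([np.array(pts)] if pts else []))
        dt = Delaunay(allpts)
        cent = allpts[dt.simplices].mean(axis=1)
        keep_poly = prep(dom.buffer(1e-9))
        keep = np.array([keep_poly.contains(Point(c)) for c in cent])
        sa = np.abs(_signed_area(allpts, dt.simplices))
        keep &= sa > 1e-9 * area
        tris = dt.simplices[keep]
        used = np.unique(tris)
        remap = -np.ones(len(allpts), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return Triangulation(allpts[used], remap[tris])

    def covers(mesh) -> bool:
        if must_cover is None or not len(must_cover):
            return True
        idx, _ = mesh.locate(must_cover)
        return bool((idx >= 0).all())

    best = None
    for dilate in (0.0, 0.25, 0.45, 0.7):
        h = float(np.sqrt(area / (0.5 * target_M)))  # ~2 triangles per h^2 cell
        lo, hi = 0.3 * h, 3.0 * h
        for _ in range(40):
            mesh = build(h, dilate)
            if mesh is not None:
                M = mesh.n_triangles
                on_target = abs(M - target_M) <= tol_frac * target_M
                if on_target and covers(mesh):
                    if best is None or abs(M - target_M) < abs(best.n_triangles - target_M):
                        best = mesh
                if on_target:
                    break
                if M > target_M:
                    lo = h
                else:
                    hi = h
            else:
                hi = h
            h = 0.5 * (lo + hi)
        if best is not None:
            break
    if best is None:
        raise ValueError(
            f"could not mesh the domain at target_M={target_M} while covering "
            "all required points")
    best.validate()
    return best
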