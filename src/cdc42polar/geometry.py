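"""Surface mesh of a spherocylindrical cell and its discrete Laplace-Beltrami operator.

The plasma membrane of a rod-shaped fission yeast cell is represented as a
closed spherocylinder: a cylinder of radius ``R`` aligned with the z axis,
capped by two hemispheres, with total tip-to-tip length ``L``.  Membrane
species diffuse on this curved surface, so the central object here is a
quasi-uniform point set on the surface together with a finite-volume
(cotangent-weight) discretization of the Laplace-Beltrami operator.

Construction strategy: points are laid out in rings of equal meridian
spacing with ring populations proportional to the local circumference
(equal-area placement), the bands between adjacent rings are stitched into
triangles, and sliver triangles are removed by Delaunay edge flips.  Per-node
Voronoi-like areas are the barycentric thirds of incident triangle areas;
edge weights are the standard half-cotangent sums.  After the flips all edge
weights are non-negative and the weight matrix is symmetric by construction,
so pure diffusion satisfies a discrete maximum principle and conserves
area-weighted mass to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "CellGeometry",
    "SurfaceMesh",
    "build_mesh",
    "laplace_beltrami",
    "tip_distance",
    "export_vtk",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder dimensions and mesh resolution.

    Parameters
    ----------
    L : float
        Tip-to-tip cell length (μm).  Must exceed ``2 R``.
    R : float
        Cylinder and cap radius (μm).
    target_cell_area : float
        Desired area of a single Voronoi cell of the discretization (μm²).
    """

    L: float = 8.0
    R: float = 2.0
    target_cell_area: float = 0.03

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"R must be positive, got {self.R}")
        if self.L <= 2 * self.R:
            raise ValueError(
                f"L must exceed 2R (L={self.L}, R={self.R}): "
                "the cylindrical segment must have positive length"
            )
        if self.target_cell_area <= 0:
            raise ValueError("target_cell_area must be positive")

    @property
    def cylinder_length(self) -> float:
        return self.L - 2.0 * self.R

    @property
    def surface_area(self) -> float:
        """Analytic area 2πR(L-2R) + 4πR² (μm²)."""
        return 2.0 * np.pi * self.R * self.cylinder_length + 4.0 * np.pi * self.R**2

    @property
    def volume(self) -> float:
        """Enclosed volume πR²(L-2R) + (4/3)πR³ (μm³)."""
        return np.pi * self.R**2 * self.cylinder_length + 4.0 / 3.0 * np.pi * self.R**3

    @property
    def meridian_length(self) -> float:
        """Pole-to-pole arc length along a meridian (μm)."""
        return np.pi * self.R + self.cylinder_length

    @property
    def max_tip_distance(self) -> float:
        """Arc-length distance from a pole to mid-cell, πR/2 + (L-2R)/2."""
        return np.pi * self.R / 2.0 + self.cylinder_length / 2.0


@dataclass
class SurfaceMesh:
    """Triangulated closed surface with finite-volume diffusion operator.

    Attributes
    ----------
    nodes : (N, 3) float array
        Point positions on the spherocylinder surface (μm).
    triangles : (T, 3) int array
        Triangle vertex indices (outward oriented).
    areas : (N,) float array
        Per-node (barycentric Voronoi) areas (μm²); sums to the surface area.
    lap : scipy.sparse.csr_matrix
        ``lap @ f`` gives the integrated flux ``Σ_j w_ij (f_j - f_i)``; divide
        by ``areas`` for the pointwise Laplace-Beltrami operator.  Symmetric
        with zero row sums.
    s : (N,) float array
        Meridian arc-length distance to the nearest tip pole (μm).
    tip_ids : (2,) int array
        Node indices of the two pole apices (tip 1 at z<0, tip 2 at z>0).
    geom : CellGeometry
    """

    nodes: np.ndarray
    triangles: np.ndarray
    areas: np.ndarray
    lap: sparse.csr_matrix
    s: np.ndarray
    tip_ids: np.ndarray
    geom: CellGeometry
    wdeg: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def integrate(self, f: np.ndarray) -> float:
        """Surface integral ∫ f da as the area-weighted sum."""
        return float(np.dot(self.areas, f))


def _meridian_profile(geom: CellGeometry, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radius ρ(t) and axial coordinate z(t) along the meridian.

    ``t`` is arc length from the south pole (z = -L/2), t ∈ [0, meridian_length].
    """
    R, zc = geom.R, geom.cylinder_length / 2.0
    qc = np.pi * R / 2.0  # quarter-circle cap meridian
    t = np.asarray(t, dtype=float)
    rho = np.empty_like(t)
    z = np.empty_like(t)
    south = t <= qc
    north = t >= qc + geom.cylinder_length
    mid = ~(south | north)
    rho[south] = R * np.sin(t[south] / R)
    z[south] = -zc - R * np.cos(t[south] / R)
    rho[mid] = R
    z[mid] = -zc + (t[mid] - qc)
    tn = geom.meridian_length - t[north]
    rho[north] = R * np.sin(tn / R)
    z[north] = zc + R * np.cos(tn / R)
    return rho, z


def _initial_points(
    geom: CellGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Ring layout: equal meridian spacing, ring size ∝ circumference.

    Returns the point array (poles first) and the per-ring index lists.
    """
    a0 = geom.target_cell_area
    d = np.sqrt(2.0 * a0 / np.sqrt(3.0))  # hex-lattice point spacing
    M = geom.meridian_length
    n_rows = max(int(round(M / (d * np.sqrt(3.0) / 2.0))), 4)
    t_rows = M * np.arange(1, n_rows) / n_rows
    rho, z = _meridian_profile(geom, t_rows)
    pts = [np.array([[0.0, 0.0, -geom.L / 2.0]]), np.array([[0.0, 0.0, geom.L / 2.0]])]
    rings: list[np.ndarray] = []
    idx = 2
    for k, (rk, zk) in enumerate(zip(rho, z)):
        nk = max(int(round(2.0 * np.pi * rk / d)), 3)
        # golden-ratio ring offsets avoid long aligned seams; small seeded
        # jitter decorrelates the mesh from a perfect lattice
        phi0 = 2.0 * np.pi * ((k + 1) * _GOLDEN % 1.0)
        jitter = rng.uniform(-0.05, 0.05, size=nk) * (2.0 * np.pi / nk)
        phi = phi0 + 2.0 * np.pi * np.arange(nk) / nk + jitter
        ring = np.column_stack([rk * np.cos(phi), rk * np.sin(phi), np.full(nk, zk)])
        pts.append(ring)
        rings.append(np.arange(idx, idx + nk))
        idx += nk
    return np.vstack(pts), rings


def _stitch_rings(pts: np.ndarray, ring_a: np.ndarray, ring_b: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the band between two adjacent rings by angular merge."""
    ang_a = np.arctan2(pts[ring_a, 1], pts[ring_a, 0])
    ang_b = np.arctan2(pts[ring_b, 1], pts[ring_b, 0])
    oa, ob = np.argsort(ang_a), np.argsort(ang_b)
    a, b = ring_a[oa], ring_b[ob]
    aa, ab = ang_a[oa], ang_b[ob]
    na, nb = len(a), len(b)
    # start ring-b pointer at the vertex nearest in angle to a[0]
    j0 = int(np.argmin(np.abs((ab - aa[0] + np.pi) % (2 * np.pi) - np.pi)))
    tris = []
    i, j = 0, 0
    # unwrapped angles relative to the start, monotone around the circle
    ua = (aa - aa[0]) % (2 * np.pi)
    ub = (ab[(j0 + np.arange(nb)) % nb] - aa[0]) % (2 * np.pi)
    ua = np.append(ua, 2 * np.pi)
    ub = np.append(ub, ub[0] + 2 * np.pi)
    b_ord = b[(j0 + np.arange(nb)) % nb]
    while i < na or j < nb:
        ai, bj = a[i % na], b_ord[j % nb]
        advance_a = j >= nb or (i < na and ua[i + 1] <= ub[j + 1])
        if advance_a:
            tris.append((ai, bj, a[(i + 1) % na]))
            i += 1
        else:
            tris.append((ai, bj, b_ord[(j + 1) % nb]))
            j += 1
    return tris


def _triangulate(pts: np.ndarray, rings: list[np.ndarray]) -> np.ndarray:
    """Closed triangulation: pole fans plus stitched inter-ring bands."""
    tris: list[tuple[int, int, int]] = []
    for pole, ring in ((0, rings[0]), (1, rings[-1])):
        ang = np.arctan2(pts[ring, 1], pts[ring, 0])
        r = ring[np.argsort(ang)]
        for k in range(len(r)):
            tris.append((pole, r[k], r[(k + 1) % len(r)]))
    for ra, rb in zip(rings[:-1], rings[1:]):
        tris.extend(_stitch_rings(pts, ra, rb))
    return np.asarray(tris, dtype=np.int64)


def _delaunay_flips(pts: np.ndarray, tri: np.ndarray, max_passes: int = 30) -> np.ndarray:
    """Flip non-Delaunay edges (negative summed opposite cotangents).

    Leaves node positions untouched; only the connectivity changes.  On
    termination every interior edge satisfies the Delaunay angle criterion,
    so all cotangent weights are non-negative.
    """

    def _cot(pa: np.ndarray, pb: np.ndarray, pc: np.ndarray) -> float:
        u, v = pb - pa, pc - pa
        cr = np.linalg.norm(np.cross(u, v))
        return float(np.dot(u, v)) / max(cr, 1e-14)

    tris: list[tuple[int, int, int]] = [tuple(t) for t in tri]
    for _ in range(max_passes):
        edges: dict[frozenset, list[tuple[int, int]]] = {}
        for ti, (a, b, c) in enumerate(tris):
            for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
                edges.setdefault(frozenset((u, v)), []).append((ti, w))
        n_flips = 0
        touched: set[int] = set()
        for e, adj in edges.items():
            if len(adj) != 2:
                continue
            (t1, a), (t2, b) = adj
            if t1 in touched or t2 in touched or a == b:
                continue
            u, v = tuple(e)
            if _cot(pts[a], pts[u], pts[v]) + _cot(pts[b], pts[u], pts[v]) < -1e-12:
                if frozenset((a, b)) in edges:
                    continue
                tris[t1] = (a, u, b)
                tris[t2] = (b, v, a)
                touched.update((t1, t2))
                n_flips += 1
        if n_flips == 0:
            break
    return np.asarray(tris, dtype=np.int64)


def _cotan_laplacian(pts: np.ndarray, tri: np.ndarray) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Half-cotangent edge weights and barycentric node areas."""
    n = pts.shape[0]
    i0, i1, i2 = tri[:, 0], tri[:, 1], tri[:, 2]
    p0, p1, p2 = pts[i0], pts[i1], pts[i2]
    # cot of the angle at each corner; the opposite edge gets the weight
    vals = []
    for pa, pb, pc in ((p0, p1, p2), (p1, p2, p0), (p2, p0, p1)):
        u = pb - pa
        v = pc - pa
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cross = np.where(cross < 1e-14, 1e-14, cross)
        cot = np.einsum("ij,ij->i", u, v) / cross
        vals.append(0.5 * cot)
    # each directed contribution mirrored so W is symmetric; hull triangles
    # cover every edge from both sides, giving (cot α + cot β)/2 per edge
    r = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0], tri[:, 2], tri[:, 0], tri[:, 1]])
    c = np.concatenate([tri[:, 2], tri[:, 0], tri[:, 1], tri[:, 1], tri[:, 2], tri[:, 0]])
    v = np.concatenate(vals + vals)
    W = sparse.coo_matrix((v, (r, c)), shape=(n, n)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    lap = W - sparse.diags(deg)
    # triangle areas -> barycentric node areas
    t_area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    areas = np.zeros(n)
    np.add.at(areas, i0, t_area / 3.0)
    np.add.at(areas, i1, t_area / 3.0)
    np.add.at(areas, i2, t_area / 3.0)
    return lap.tocsr(), areas


def tip_distance(geom: CellGeometry, nodes: np.ndarray) -> np.ndarray:
    """Meridian arc length from each node to the nearest tip pole (μm).

    Computed analytically from the axial coordinate: on a cap the distance is
    ``R × (polar angle from the pole)``; on the cylinder it is the quarter
    meridian ``πR/2`` plus the axial distance to the nearer cap junction.
    """
    R, zc = geom.R, geom.cylinder_length / 2.0
    az = np.abs(np.asarray(nodes)[:, 2])
    on_cap = az > zc
    s = np.empty_like(az)
    cosang = np.clip((az[on_cap] - zc) / R, -1.0, 1.0)
    s[on_cap] = R * np.arccos(cosang)
    s[~on_cap] = np.pi * R / 2.0 + (zc - az[~on_cap])
    return s


def build_mesh(geom: CellGeometry, seed: int = 0) -> SurfaceMesh:
    """Build the quasi-uniform surface mesh and its diffusion operator.

    Raises
    ------
    ValueError
        If ``target_cell_area`` is so coarse that fewer than 200 nodes would
        cover the surface.
    """
    n_expected = geom.surface_area / geom.target_cell_area
    if n_expected < 200:
        raise ValueError(
            f"target_cell_area={geom.target_cell_area} μm² would give only "
            f"~{n_expected:.0f} nodes (< 200); choose a finer resolution"
        )
    rng = np.random.default_rng(seed)
    pts, rings = _initial_points(geom, rng)
    tri = _triangulate(pts, rings)
    tri = _delaunay_flips(pts, tri)
    lap, areas = _cotan_laplacian(pts, tri)
    s = tip_distance(geom, pts)
    mesh = SurfaceMesh(
        nodes=pts,
        triangles=tri,
        areas=areas,
        lap=lap,
        s=s,
        tip_ids=np.array([0, 1]),
        geom=geom,
        wdeg=np.asarray(-lap.diagonal()),
    )
    return mesh


def laplace_beltrami(mesh: SurfaceMesh, f: np.ndarray) -> np.ndarray:
    """Apply the discrete Laplace-Beltrami operator to a per-node field.

    Returns ``(Δ_S f)_i = (1/A_i) Σ_j w_ij (f_j - f_i)`` (units of f per μm²).
    The area-weighted sum of the result vanishes identically (closed surface).
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (mesh.n_nodes,):
        raise ValueError(f"field has shape {f.shape}, expected ({mesh.n_nodes},)")
    return (mesh.lap @ f) / mesh.areas


def export_vtk(mesh: SurfaceMesh, path, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh and per-node scalars as legacy ASCII VTK PolyData."""
    data = {"s": mesh.s, "area": mesh.areas}
    if point_data:
        data.update(point_data)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspherocylinder surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        ntri = mesh.triangles.shape[0]
        fh.write(f"POLYGONS {ntri} {4 * ntri}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, values in data.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.6g}" for v in np.asarray(values)) + "\n")
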