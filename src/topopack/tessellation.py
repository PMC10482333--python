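"""Delaunay tessellation, alpha-complex, and bulk/boundary classification.

The Delaunay tessellation DT(X) of a 3D point cloud X is the simplicial
complex dual to the Voronoi diagram: a set of tetrahedra whose circumspheres
contain no other input point. It links each point to its geometric nearest
neighbors and is the combinatorial backbone of every downstream statistic.

Boundary handling follows the touching-sphere definition: a point x_i is a
*boundary point* at scale alpha if an empty sphere of radius alpha can touch
it, i.e. there is a location y with ||x_i - y|| = alpha and ||x_j - y|| >= alpha
for every other point. Because the Voronoi cell of x_i is convex and contains
x_i, such a y exists exactly when the cell of x_i reaches distance alpha from
x_i; for interior points the farthest cell vertex is the largest circumcenter
of an incident Delaunay tetrahedron, and hull points have unbounded cells.
This gives an exact O(#tetrahedra) classification equivalent to membership in
the boundary of the alpha-complex, and it is validated against a brute-force
sphere-probing oracle in the test suite.
"""

from __future__ import annotations

import dataclasses
from functools import cached_property

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .cloud import PointCloud, median_nn_distance
from .errors import DegenerateCloudError, InputError, InsufficientPointsError

__all__ = [
    "SimplicialComplex",
    "BulkMask",
    "build_delaunay",
    "alpha_complex",
    "classify_boundary",
    "circumspheres",
    "default_alpha",
    "write_tetrahedra",
    "read_tetrahedra",
]

#: Default jitter applied to degenerate (cospherical) inputs, as a fraction of
#: the median nearest-neighbor distance.
DEFAULT_JITTER_SCALE = 1e-6


@dataclasses.dataclass(frozen=True)
class SimplicialComplex:
    """A tetrahedral complex over indexed vertices (0-based).

    ``points`` carries the coordinates actually tessellated — identical to the
    input unless a degeneracy-resolving jitter was applied, in which case the
    jittered coordinates are recorded here.
    """

    n_vertices: int
    tetrahedra: np.ndarray  # (m, 4) int, each row sorted ascending
    points: np.ndarray | None = None

    def __post_init__(self) -> None:
        tets = np.asarray(self.tetrahedra, dtype=np.int64)
        if tets.size == 0:
            tets = tets.reshape(0, 4)
        if tets.ndim != 2 or tets.shape[1] != 4:
            raise InputError("tetrahedra must be an (m, 4) index array")
        tets = np.sort(tets, axis=1)
        if tets.shape[0]:
            if tets.min() < 0 or tets.max() >= self.n_vertices:
                raise InputError("tetrahedron index out of range")
            if np.any(np.diff(tets, axis=1) == 0):
                raise InputError("tetrahedron with repeated vertex")
        # canonical row order for determinism
        order = np.lexsort(tets.T[::-1])
        object.__setattr__(self, "tetrahedra", tets[order])

    @property
    def n_tetrahedra(self) -> int:
        return self.tetrahedra.shape[0]

    @cached_property
    def faces(self) -> np.ndarray:
        """All triangular faces induced by the tetrahedra, one row each (sorted)."""
        t = self.tetrahedra
        f = np.concatenate(
            [t[:, [0, 1, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 3]], t[:, [1, 2, 3]]]
        )
        return np.unique(f, axis=0)

    @cached_property
    def edges(self) -> np.ndarray:
        t = self.tetrahedra
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        e = np.concatenate([t[:, list(p)] for p in pairs])
        return np.unique(e, axis=0)

    @cached_property
    def vertex_tetrahedra(self) -> list[np.ndarray]:
        """For each vertex, the row indices of its incident tetrahedra."""
        flat = self.tetrahedra.ravel()
        rows = np.repeat(np.arange(self.n_tetrahedra), 4)
        order = np.argsort(flat, kind="stable")
        flat, rows = flat[order], rows[order]
        bounds = np.searchsorted(flat, np.arange(self.n_vertices + 1))
        return [rows[bounds[i] : bounds[i + 1]] for i in range(self.n_vertices)]

    @cached_property
    def hull_vertices(self) -> np.ndarray:
        """Vertices on the convex hull (on a face incident to exactly one tet)."""
        t = self.tetrahedra
        f = np.concatenate(
            [t[:, [0, 1, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 3]], t[:, [1, 2, 3]]]
        )
        uniq, counts = np.unique(f, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])


@dataclasses.dataclass(frozen=True)
class BulkMask:
    """Per-vertex boundary flags at a given probing radius alpha."""

    is_boundary: np.ndarray  # bool per vertex
    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "is_boundary", np.asarray(self.is_boundary, dtype=bool)
        )
        if self.alpha <= 0:
            raise InputError("alpha must be positive")

    @property
    def bulk_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_boundary)


def circumspheres(points: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circumcenters and circumradii of tetrahedra (vectorized).

    Solves 2 (v_k - v_0) . c = |v_k|^2 - |v_0|^2 for each tetrahedron.
    """
    pts = points[tets]  # (m, 4, 3)
    a = pts[:, 0]
    A = 2.0 * (pts[:, 1:] - a[:, None, :])  # (m, 3, 3)
    b = np.einsum("mij,mij->mi", pts[:, 1:], pts[:, 1:]) - np.einsum(
        "mj,mj->m", a, a
    )[:, None]
    # flat (zero-volume) tetrahedra have no circumsphere: radius = inf
    det = np.linalg.det(A)
    scale = np.prod(np.linalg.norm(A, axis=2), axis=1)
    good = np.abs(det) > 1e-12 * np.maximum(scale, 1e-300)
    centers = np.full((len(tets), 3), np.nan)
    radii = np.full(len(tets), np.inf)
    if np.any(good):
        centers[good] = np.linalg.solve(A[good], b[good][..., None])[..., 0]
        radii[good] = np.linalg.norm(centers[good] - a[good], axis=1)
    return centers, radii


def default_alpha(cloud: PointCloud, multiple: float = 4.0) -> float:
    """Scale-free default probing radius: ``multiple`` x median NN distance."""
    return multiple * median_nn_distance(cloud.coords)


def _is_degenerate(points: np.ndarray, dt: Delaunay, rtol: float = 1e-9) -> bool:
    """Detect near-cospherical degeneracy from an existing tessellation.

    For each tetrahedron, the vertex opposite each neighboring tetrahedron must
    lie strictly outside the circumsphere; if it sits on the sphere to within
    ``rtol`` the triangulation is combinatorially ambiguous.
    """
    tets = dt.simplices
    centers, radii = circumspheres(points, tets)
    if not np.all(np.isfinite(radii)):
        return True  # flat simplices: Qhull tie-broke a cospherical input
    for k in range(4):
        nb = dt.neighbors[:, k]
        has_nb = nb >= 0
        if not np.any(has_nb):
            continue
        # vertex of the neighbor tet not shared with this tet
        this = tets[has_nb]
        other = tets[nb[has_nb]]
        shared = (other[:, :, None] == this[:, None, :]).any(axis=2)
        opp = other[~shared]  # exactly one non-shared vertex per neighbor pair
        d = np.linalg.norm(points[opp] - centers[has_nb], axis=1)
        if np.any(np.abs(d - radii[has_nb]) <= rtol * radii[has_nb]):
            return True
    return False


def build_delaunay(
    cloud: PointCloud, jitter_scale: float = DEFAULT_JITTER_SCALE
) -> SimplicialComplex:
    """Delaunay tetrahedralization, resolving degeneracies by seeded jitter.

    Perfect lattices and other inputs with >= 5 cospherical points have an
    ambiguous Delaunay triangulation. Rather than symbolic perturbation, a
    reproducible Gaussian jitter of magnitude ``jitter_scale`` x (median NN
    distance) is applied — seeded from the cloud's ``rng_seed`` — and the
    jittered coordinates are recorded on the returned complex.

    Parameters
    ----------
    cloud:
        At least 5 points, not all coplanar.
    jitter_scale:
        Jitter magnitude as a fraction of the median nearest-neighbor
        distance; 0 disables jitter.
    """
    if cloud.n < 5:
        raise InsufficientPointsError(
            f"insufficient points: need >= 5 for a 3D tessellation, got {cloud.n}"
        )
    if jitter_scale < 0:
        raise InputError("jitter_scale must be >= 0")
    points = cloud.coords

    def _tessellate(pts: np.ndarray) -> Delaunay:
        try:
            dt = Delaunay(pts)
        except QhullError as exc:
            raise DegenerateCloudError(f"degenerate cloud: {exc}") from exc
        if dt.simplices.shape[1] != 4:
            raise DegenerateCloudError("degenerate cloud: points are coplanar")
        return dt

    dup = len(np.unique(points, axis=0)) < len(points)
    if dup and jitter_scale == 0:
        raise InputError("coincident points and jitter disabled")
    jittered = False
    if not dup:
        dt = _tessellate(points)
    if jitter_scale > 0 and (dup or _is_degenerate(points, dt)):
        scale = jitter_scale * median_nn_distance(points)
        rng = np.random.default_rng(
            cloud.rng_seed if cloud.rng_seed is not None else 0
        )
        points = points + rng.normal(scale=scale, size=points.shape)
        if len(np.unique(points, axis=0)) < len(points):
            raise InputError("coincident points persist after jitter")
        dt = _tessellate(points)
        jittered = True
    return SimplicialComplex(
        n_vertices=cloud.n,
        tetrahedra=dt.simplices,
        points=points if jittered else cloud.coords,
    )


def alpha_complex(
    dt: SimplicialComplex, cloud: PointCloud, alpha: float
) -> SimplicialComplex:
    """Subcomplex of tetrahedra with circumsphere radius < alpha.

    The alpha-complex retains the tessellation at spatial scale alpha; its
    boundary separates bulk from boundary points.
    """
    if alpha <= 0:
        raise InputError("alpha must be positive")
    points = dt.points if dt.points is not None else cloud.coords
    if dt.n_tetrahedra == 0:
        return dataclasses.replace(dt)
    _, radii = circumspheres(points, dt.tetrahedra)
    keep = radii < alpha
    return SimplicialComplex(
        n_vertices=dt.n_vertices, tetrahedra=dt.tetrahedra[keep], points=points
    )


def classify_boundary(
    dt: SimplicialComplex, cloud: PointCloud, alpha: float
) -> BulkMask:
    """Classify every vertex as bulk or boundary at probing radius alpha.

    A vertex is boundary iff an empty sphere of radius alpha can touch it.
    Equivalently (see module docstring): it lies on the convex hull, or some
    incident Delaunay tetrahedron has circumradius >= alpha — i.e. the vertex
    is on the boundary of the alpha-complex or outside it entirely.
    """
    if alpha <= 0:
        raise InputError("alpha must be positive")
    points = dt.points if dt.points is not None else cloud.coords
    is_boundary = np.zeros(dt.n_vertices, dtype=bool)
    is_boundary[dt.hull_vertices] = True
    # vertices in no tetrahedron at all can always be touched
    in_any = np.zeros(dt.n_vertices, dtype=bool)
    in_any[np.unique(dt.tetrahedra)] = True
    is_boundary[~in_any] = True
    if dt.n_tetrahedra:
        _, radii = circumspheres(points, dt.tetrahedra)
        far = np.unique(dt.tetrahedra[radii >= alpha])
        is_boundary[far] = True
    return BulkMask(is_boundary=is_boundary, alpha=float(alpha))


# ---------------------------------------------------------------------------
# Interchange


def write_tetrahedra(dt: SimplicialComplex, path, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write(f"# n_vertices: {dt.n_vertices}\n")
        fh.write("i,j,k,l\n")
        for row in dt.tetrahedra:
            fh.write(",".join(str(v) for v in row) + "\n")


def read_tetrahedra(path) -> SimplicialComplex:
    import pandas as pd

    n_vertices = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "n_vertices:" in line:
                n_vertices = int(line.split("n_vertices:")[1].strip())
            elif not line.startswith("#"):
                break
    tets = pd.read_csv(path, comment="#").to_numpy(dtype=np.int64)
    if n_vertices is None:
        n_vertices = int(tets.max()) + 1 if tets.size else 0
    return SimplicialComplex(n_vertices=n_vertices, tetrahedra=tets)
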