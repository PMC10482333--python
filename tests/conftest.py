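"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from topopack import GeneratorSpec, PointCloud, generate


# ---------------------------------------------------------------------------
# Clouds


@pytest.fixture
def tetra_centroid_cloud() -> PointCloud:
    """Regular tetrahedron plus its centroid: the canonical 5-point fixture.

    Its Delaunay tessellation is exactly the 4 tetrahedra formed by the
    centroid with each face of the outer tetrahedron.
    """
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return PointCloud(np.vstack([v, v.mean(axis=0)]), sample_id="tetra+centroid")


@pytest.fixture
def poisson_factory():
    def make(n: int = 200, seed: int = 0) -> PointCloud:
        return generate(GeneratorSpec(kind="poisson", n=n, seed=seed))

    return make


# ---------------------------------------------------------------------------
# Brute-force Delaunay oracle


def brute_force_delaunay(points: np.ndarray, tol: float = 1e-9) -> set:
    """All 4-subsets passing the empty-circumsphere test (tiny n only)."""
    n = len(points)
    out = set()
    for combo in itertools.combinations(range(n), 4):
        p = points[list(combo)]
        A = 2.0 * (p[1:] - p[0])
        if abs(np.linalg.det(A)) < tol:
            continue  # coplanar
        b = np.einsum("ij,ij->i", p[1:], p[1:]) - p[0] @ p[0]
        center = np.linalg.solve(A, b)
        r = np.linalg.norm(center - p[0])
        others = [i for i in range(n) if i not in combo]
        if not others:
            out.add(combo)
            continue
        d = np.linalg.norm(points[others] - center, axis=1)
        if np.all(d > r * (1 + tol)):
            out.add(combo)
    return out


# ---------------------------------------------------------------------------
# Sphere-probing boundary oracle


def sphere_probe_boundary(
    points: np.ndarray, alpha: float, n_dirs: int = 800, seed: int = 0
) -> np.ndarray:
    """Brute-force boundary classification by searching for an empty
    touching sphere.

    A point x_i is boundary iff some location y with ||y - x_i|| = alpha has
    all other points at distance >= alpha. The search uses the fact that any
    y' whose nearest input point is x_i at distance >= alpha yields a witness
    by sliding y' toward x_i (distances to other points can only stay >=
    alpha along the way). Candidates: (a) random directions at several radii,
    (b) circumcenters of all 4-subsets are not needed — the circumcenters of
    nearby empty spheres are probed through (a) plus candidates far outside
    the cloud. Purely distance-based; independent of any alpha-complex code.
    """
    rng = np.random.default_rng(seed)
    n = len(points)
    dirs = rng.normal(size=(n_dirs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    diameter = float(np.linalg.norm(points.max(0) - points.min(0)))
    radii = [alpha, 2 * alpha, alpha + diameter, 10 * (alpha + diameter)]
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        found = False
        for r in radii:
            cand = points[i] + r * dirs  # (n_dirs, 3)
            d_all = np.linalg.norm(cand[:, None, :] - points[None], axis=2)
            d_self = d_all[:, i]
            d_others = np.delete(d_all, i, axis=1).min(axis=1)
            # y' valid if x_i is (weakly) nearest and at distance >= alpha
            if np.any((d_self >= alpha - 1e-12) & (d_others >= d_self - 1e-12)):
                found = True
                break
        out[i] = found
    return out


def targeted_boundary_witness(
    points: np.ndarray, tets: np.ndarray, alpha: float
) -> np.ndarray:
    """Exact boundary witnesses from empty-circumsphere centers.

    For each vertex, if some incident Delaunay tetrahedron has an (empty)
    circumsphere of radius >= alpha, sliding its center toward the vertex
    produces a touching empty alpha-sphere. Verified here directly from
    point-to-point distances, independent of the production classifier.
    """
    from topopack.tessellation import circumspheres

    centers, radii = circumspheres(points, tets)
    n = len(points)
    out = np.zeros(n, dtype=bool)
    for t_idx in np.flatnonzero(radii >= alpha):
        c, r = centers[t_idx], radii[t_idx]
        d = np.linalg.norm(points - c, axis=1)
        assert d.min() >= r * (1 - 1e-9)  # empty circumsphere sanity
        out[tets[t_idx]] = True
    return out


def targeted_hull_witness(points: np.ndarray, alpha: float) -> np.ndarray:
    """Exact boundary witnesses for convex-hull vertices.

    For a hull vertex, a far-away probe along an interior direction of its
    normal cone has the vertex as the (strictly) nearest input point, which
    yields a touching empty alpha-sphere by the sliding argument. The witness
    is verified numerically from raw distances.
    """
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    n = len(points)
    out = np.zeros(n, dtype=bool)
    normals: dict[int, list] = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        for v in simplex:
            normals.setdefault(int(v), []).append(eq[:3])
    diameter = float(np.linalg.norm(points.max(0) - points.min(0)))
    R = 100.0 * (diameter + alpha)
    for v, ns in normals.items():
        d = np.mean(ns, axis=0)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        y = points[v] + R * d / norm
        dist = np.linalg.norm(points - y, axis=1)
        if dist[v] <= dist.min() + 1e-9 and dist[v] >= alpha:
            out[v] = True
    return out


# ---------------------------------------------------------------------------
# Motif-isomorphism oracle (igraph VF2 on the colored incidence graph)


def motifs_isomorphic(m1, m2) -> bool:
    """Exact center-fixing isomorphism test, independent of canonical labels.

    Encodes each motif as a bipartite vertex/tetrahedron incidence graph with
    colors (center / neighbor / tetrahedron) and runs VF2.
    """
    import igraph

    if m1.n_neighbors != m2.n_neighbors or len(m1.tetrahedra) != len(
        m2.tetrahedra
    ):
        return False

    def encode(m):
        nv = m.n_neighbors + 1
        g = igraph.Graph()
        g.add_vertices(nv + len(m.tetrahedra))
        colors = [0] + [1] * m.n_neighbors + [2] * len(m.tetrahedra)
        edges = []
        for ti, t in enumerate(m.tetrahedra):
            for v in t:
                edges.append((v, nv + ti))
        g.add_edges(edges)
        return g, colors

    g1, c1 = encode(m1)
    g2, c2 = encode(m2)
    return g1.isomorphic_vf2(g2, color1=c1, color2=c2)


def relabel_motif(motif, rng: np.random.Generator):
    """Random center-fixing relabeling of a motif's neighbors."""
    from topopack import Motif

    k = motif.n_neighbors
    perm = rng.permutation(k) + 1
    mapping = {0: 0, **{i + 1: int(perm[i]) for i in range(k)}}
    tets = tuple(tuple(sorted(mapping[v] for v in t)) for t in motif.tetrahedra)
    return Motif(n_neighbors=k, tetrahedra=tets)
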