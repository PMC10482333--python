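"""Topological atlases: MDS embeddings, trajectory curvature, group tests.

A collection of samples with pairwise topological distances is embedded into
a low-dimensional *atlas* by classical (Torgerson) multidimensional scaling:
double-center the squared distance matrix, eigendecompose, and use the top
eigenvector columns scaled by the square root of their eigenvalues as
principal-component coordinates. Topological distance matrices need not be
Euclidean, so negative eigenvalue mass is reported (never silently dropped).

Ordered series of samples (e.g. developmental time courses) trace
trajectories in motif space; their local geometry is quantified by the Menger
curvature of consecutive distance triples — the inverse circumradius of three
points known only through their pairwise distances. Group differences are
assessed with a label-permutation test on the distance matrix using the
between-minus-within mean distance statistic.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np

from .distance import DistanceMatrix, _as_vector, _solver
from .errors import InputError, NonMetricTripleError
from .flipgraph import FlipGraph
from .motifs import MotifDistribution

__all__ = [
    "Embedding",
    "TrajectoryCurvature",
    "classical_mds",
    "menger_curvature",
    "trajectory_curvature",
    "group_permutation_test",
    "convex_hull_membership",
    "write_embedding",
    "write_curvature_series",
]


@dataclasses.dataclass(frozen=True)
class Embedding:
    """Classical MDS coordinates in descending-eigenvalue order."""

    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # all n eigenvalues, descending
    stress: float  # relative magnitude of truncated negative eigenvalue mass
    labels: tuple = ()


@dataclasses.dataclass(frozen=True)
class TrajectoryCurvature:
    """Menger curvature per interior sample of an ordered series.

    Units are 1/distance; entries are NaN where the triple is degenerate
    (zero distances)."""

    curvatures: np.ndarray
    indices: np.ndarray  # sample index of each interior point
    window: int


def classical_mds(dm: DistanceMatrix, k: int = 2) -> Embedding:
    """Torgerson MDS of a distance matrix.

    B = -1/2 J D^2 J with J the centering projector; coordinates are the top-k
    eigenvector columns scaled by sqrt(eigenvalue). Negative eigenvalues are
    truncated to zero and their relative magnitude is reported as ``stress``.
    If fewer than k eigenvalues are positive the remaining columns are
    zero-padded with a warning.
    """
    n = len(dm.labels)
    if not 1 <= k <= n - 1:
        raise InputError(f"embedding dimension k={k} must be in [1, {n - 1}]")
    D2 = dm.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    n_pos = int(np.sum(lam > 0))
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; zero-padding columns {n_pos}..{k - 1}",
            stacklevel=2,
        )
    coords = np.zeros((n, k))
    kk = min(k, n_pos)
    coords[:, :kk] = vec[:, :kk] * np.sqrt(lam[:kk])
    total = float(np.abs(lam).sum())
    neg = float(np.abs(lam[lam < 0]).sum())
    stress = neg / total if total > 0 else 0.0
    # enforce exact column centering (J guarantees it up to round-off)
    coords -= coords.mean(axis=0, keepdims=True)
    return Embedding(
        coordinates=coords, eigenvalues=lam, stress=stress, labels=dm.labels
    )


def menger_curvature(d_ab: float, d_bc: float, d_ac: float, tol: float = 1e-12) -> float:
    """Inverse circumradius of a triple known through pairwise distances.

    curvature = 4 * Area / (d_ab * d_bc * d_ac), with the area from Heron's
    formula in Kahan's numerically stable ordering. Zero exactly when the
    triple is degenerate-collinear (triangle inequality tight).
    """
    sides = sorted((float(d_ab), float(d_bc), float(d_ac)), reverse=True)
    a, b, c = sides
    if c <= 0:
        raise NonMetricTripleError("non-metric triple: nonpositive distance")
    scale = max(a, 1.0)
    if c - (a - b) < -tol * scale:
        raise NonMetricTripleError(
            f"non-metric triple: triangle inequality violated by {(a - b) - c:.3e}"
        )
    # Kahan's stable Heron factors, with tiny negatives from round-off clamped
    t1 = a + (b + c)
    t2 = max(c - (a - b), 0.0)
    t3 = c + (a - b)
    t4 = max(a + (b - c), 0.0)
    area = 0.25 * math.sqrt(t1 * t2 * t3 * t4)
    return 4.0 * area / (a * b * c)


def trajectory_curvature(
    dists: list[MotifDistribution],
    graph: FlipGraph,
    spacing: int = 1,
) -> TrajectoryCurvature:
    """Menger curvature along an ordered series of distributions.

    For each interior index t the TDDs among (t - spacing, t, t + spacing)
    are computed and converted to a curvature; degenerate triples (repeated
    or coincident distributions) yield NaN.
    """
    if spacing < 1:
        raise InputError("spacing must be >= 1")
    n = len(dists)
    if n < 2 * spacing + 1:
        raise InputError(f"need at least {2 * spacing + 1} samples, got {n}")
    solver = _solver(graph)
    vectors = [_as_vector(d, graph) for d in dists]

    def _tdd(i: int, j: int) -> float:
        phi = solver.solve(vectors[i] - vectors[j])
        return float(np.abs(graph.incidence @ phi).sum())

    indices = np.arange(spacing, n - spacing)
    curv = np.empty(indices.size)
    for out, t in enumerate(indices):
        d1 = _tdd(t - spacing, t)
        d2 = _tdd(t, t + spacing)
        d3 = _tdd(t - spacing, t + spacing)
        if min(d1, d2, d3) <= 0:
            curv[out] = np.nan
            continue
        try:
            curv[out] = menger_curvature(d1, d2, d3)
        except NonMetricTripleError:
            curv[out] = np.nan
    return TrajectoryCurvature(curvatures=curv, indices=indices, window=spacing)


def group_permutation_test(
    dm: DistanceMatrix,
    labels: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation test for pairwise group differences on a distance matrix.

    For each group pair the statistic is (mean between-group distance) -
    (mean within-group distance, pooled over the two groups); the null is
    generated by permuting the labels of the samples in the pair. When the
    number of distinct label assignments is at most ``n_perm`` the test is
    exact — every assignment is enumerated and p = #{stat >= observed} /
    #assignments — otherwise ``n_perm`` random permutations are drawn and
    p = (1 + #{permuted stat >= observed}) / (1 + n_perm). The statistic is
    this package's own choice (a standard distance-matrix construction).
    Groups with fewer than 2 samples are excluded with a warning.
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    labels = [str(x) for x in labels]
    if len(labels) != len(dm.labels):
        raise InputError("one group label per sample required")
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(labels):
        groups.setdefault(g, []).append(i)
    for g in [g for g, idx in groups.items() if len(idx) < 2]:
        warnings.warn(f"group {g!r} has < 2 samples; excluded", stacklevel=2)
        del groups[g]
    if len(groups) < 2:
        raise InputError("need >= 2 groups with >= 2 samples each")
    rng = np.random.default_rng(seed)
    V = dm.values
    results = {}
    for ga, gb in itertools.combinations(sorted(groups), 2):
        idx = np.array(groups[ga] + groups[gb])
        na = len(groups[ga])
        sub = V[np.ix_(idx, idx)]
        m = len(idx)
        mask_a = np.zeros(m, dtype=bool)
        mask_a[:na] = True

        def stat(mask: np.ndarray) -> float:
            between = sub[np.ix_(mask, ~mask)]
            wa = sub[np.ix_(mask, mask)]
            wb = sub[np.ix_(~mask, ~mask)]
            iu_a = np.triu_indices(mask.sum(), 1)
            iu_b = np.triu_indices((~mask).sum(), 1)
            within = np.concatenate([wa[iu_a], wb[iu_b]])
            return float(between.mean() - within.mean())

        observed = stat(mask_a)
        n_exact = math.comb(m, na)
        if n_exact <= n_perm:
            count = 0
            for combo in itertools.combinations(range(m), na):
                pm = np.zeros(m, dtype=bool)
                pm[list(combo)] = True
                if stat(pm) >= observed:
                    count += 1
            p_value = count / n_exact
            effective = n_exact
        else:
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(m)
                pm = np.zeros(m, dtype=bool)
                pm[perm[:na]] = True
                if stat(pm) >= observed:
                    count += 1
            p_value = (1 + count) / (1 + n_perm)
            effective = n_perm
        results[(ga, gb)] = {
            "statistic": observed,
            "p_value": p_value,
            "n_perm": effective,
        }
    return results


def convex_hull_membership(
    embedding: Embedding, reference: np.ndarray
) -> np.ndarray:
    """Whether each sample lies inside the convex hull of reference samples,
    using the first three embedding components — e.g. which abiotic systems
    fall inside the hull spanned by the living systems in an atlas."""
    from scipy.spatial import Delaunay as _Delaunay

    coords = embedding.coordinates[:, : min(3, embedding.coordinates.shape[1])]
    ref = np.asarray(reference)
    if ref.dtype == bool:
        ref_pts = coords[ref]
    else:
        ref_pts = coords[np.asarray(ref, dtype=int)]
    if ref_pts.shape[0] < coords.shape[1] + 1:
        raise InputError("too few reference samples for a hull")
    hull = _Delaunay(ref_pts)
    return hull.find_simplex(coords) >= 0


def write_curvature_series(tc: TrajectoryCurvature, path, comments: list[str] | None = None) -> None:
    """Two-column (sample index, curvature) table; NaN marks degenerate triples."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write(f"# window: {tc.window}\n")
        fh.write("index,curvature\n")
        for i, c in zip(tc.indices, tc.curvatures):
            fh.write(f"{i},{c:.17g}\n")


def write_embedding(embedding: Embedding, path, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write(
            "# eigenvalues: "
            + ",".join(f"{v:.17g}" for v in embedding.eigenvalues)
            + "\n"
        )
        fh.write(f"# stress: {embedding.stress:.17g}\n")
        k = embedding.coordinates.shape[1]
        fh.write("sample," + ",".join(f"pc{i + 1}" for i in range(k)) + "\n")
        labels = embedding.labels or tuple(
            str(i) for i in range(embedding.coordinates.shape[0])
        )
        for label, row in zip(labels, embedding.coordinates):
            fh.write(label + "," + ",".join(f"{v:.17g}" for v in row) + "\n")
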