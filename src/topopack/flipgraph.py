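"""The flip graph: motifs as vertices, elementary transitions as edges.

Motifs of a point in a 3D Delaunay tessellation change through discrete
topological transitions when points move: bistellar flips. A 2-3 flip replaces
two tetrahedra sharing a triangular face by three tetrahedra around the
opposite edge; a 3-2 flip is its inverse. The *flip graph* connects two
canonical motifs when one elementary move maps one to the other; it carries
the signed edge-vertex incidence matrix D (one +1 and one -1 per edge row)
and the graph Laplacian L = D^T D used by the topological diffusion distance.

Because no exhaustive catalogue of realizable 3D motifs exists, graphs are
built from the motifs actually observed in data, optionally augmented by a
bounded breadth-first expansion through combinatorial flip moves and by
empirically harvested transitions (re-tessellating a perturbed cloud and
recording which motifs changed into which). Residual disconnected components
are joined by explicit bridge edges — reported loudly, since they stand in
for unexplored paths through motif space.
"""

from __future__ import annotations

import dataclasses
import warnings
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .cloud import PointCloud, median_nn_distance
from .errors import InputError
from .motifs import Motif, MotifDistribution, extract_motif, motif_from_key
from .tessellation import build_delaunay

__all__ = [
    "FlipGraph",
    "enumerate_flip_neighbors",
    "flip_neighbor_keys",
    "empirical_flip_edges",
    "build_flip_graph",
    "graph_from_edges",
    "write_flip_graph",
    "read_flip_graph",
]


@dataclasses.dataclass(frozen=True, eq=False)
class FlipGraph:
    """Vertices (canonical keys), edges, incidence and Laplacian."""

    vertices: tuple  # canonical keys, fixed order
    edges: np.ndarray  # (E, 2) int, each row (i, j) with i < j
    incidence: sp.csr_matrix  # D: edges x vertices, +1 at i, -1 at j
    laplacian: sp.csc_matrix  # L = D^T D
    component_ids: np.ndarray  # pre-bridge component id per vertex
    bridges: tuple = ()  # bridge edges (i, j) added to restore connectivity

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def index(self) -> dict:
        if not hasattr(self, "_index"):
            object.__setattr__(
                self, "_index", {k: i for i, k in enumerate(self.vertices)}
            )
        return self._index


# ---------------------------------------------------------------------------
# Bistellar moves


def _flip_results(motif: Motif) -> list[Motif]:
    """Raw (uncanonicalized) motifs one bistellar move away.

    2-3 moves act on faces shared by exactly two tetrahedra; 3-2 moves on
    edges shared by exactly three tetrahedra forming a bipyramid. Moves that
    would duplicate an existing tetrahedron are skipped.
    """
    tets = set(motif.tetrahedra)
    k = motif.n_neighbors
    results = []

    face_map: dict[tuple, list] = {}
    edge_map: dict[tuple, list] = {}
    for t in tets:
        for i in range(4):
            face = t[:i] + t[i + 1 :]
            face_map.setdefault(face, []).append(t)
        for i in range(4):
            for j in range(i + 1, 4):
                edge_map.setdefault((t[i], t[j]), []).append(t)

    # 2-3 flips
    for face, pair in face_map.items():
        if len(pair) != 2:
            continue
        t1, t2 = pair
        d = next(v for v in t1 if v not in face)
        e = next(v for v in t2 if v not in face)
        new = [tuple(sorted((d, e) + f2)) for f2 in
               [(face[0], face[1]), (face[0], face[2]), (face[1], face[2])]]
        if any(t in tets for t in new):
            continue
        out = (tets - {t1, t2}) | set(new)
        results.append(Motif(n_neighbors=k, tetrahedra=tuple(out)))

    # 3-2 flips
    for edge, trio in edge_map.items():
        if len(trio) != 3:
            continue
        apexes = set()
        for t in trio:
            apexes.update(v for v in t if v not in edge)
        if len(apexes) != 3:
            continue  # not a bipyramid over this edge
        a, b, c = sorted(apexes)
        new = [tuple(sorted((a, b, c, edge[0]))), tuple(sorted((a, b, c, edge[1])))]
        if any(t in tets for t in new):
            continue
        out = (tets - set(trio)) | set(new)
        results.append(Motif(n_neighbors=k, tetrahedra=tuple(out)))

    return results


def enumerate_flip_neighbors(motif: Motif) -> set:
    """Canonical motifs reachable by one bistellar move (excluding itself)."""
    own = motif.canonical_key
    out = {}
    for r in _flip_results(motif):
        key = r.canonical_key
        if key != own:
            out.setdefault(key, r)
    return set(out.values())


@lru_cache(maxsize=500_000)
def flip_neighbor_keys(key: str) -> tuple:
    """Canonical keys one flip away from the motif with canonical key ``key``.

    Memoized process-wide: flip adjacency depends only on the canonical key,
    and motif supports overlap heavily across samples.
    """
    motif = motif_from_key(key)
    keys = {r.canonical_key for r in _flip_results(motif)}
    keys.discard(key)
    return tuple(sorted(keys))


# ---------------------------------------------------------------------------
# Empirical transition harvesting


def empirical_flip_edges(
    cloud: PointCloud,
    n_kicks: int = 20,
    kick_scale: float = 0.05,
    seed: int = 0,
) -> set:
    """Candidate flip edges harvested by perturb-and-retessellate.

    Each kick displaces every point by an isotropic Gaussian of standard
    deviation ``kick_scale`` x (median NN distance) and re-tessellates; for
    every center whose canonical motif changed, the (old key, new key) pair is
    recorded. Deterministic given ``seed``.
    """
    if n_kicks < 1:
        raise InputError("n_kicks must be >= 1")
    if kick_scale <= 0:
        raise InputError("kick_scale must be positive")
    dt0 = build_delaunay(cloud)
    base_keys = _all_center_keys(dt0)
    scale = kick_scale * median_nn_distance(cloud.coords)
    rng = np.random.default_rng(seed)
    edges = set()
    for _ in range(n_kicks):
        kicked = cloud.with_coords(cloud.coords + rng.normal(scale=scale, size=cloud.coords.shape))
        dtk = build_delaunay(kicked, jitter_scale=0.0)
        for center, old in base_keys.items():
            if dtk.vertex_tetrahedra[center].size == 0:
                continue
            new = extract_motif(dtk, center).canonical_key
            if new != old:
                edges.add((old, new) if old < new else (new, old))
    return edges


def _all_center_keys(dt) -> dict:
    keys = {}
    for center in range(dt.n_vertices):
        if dt.vertex_tetrahedra[center].size:
            keys[center] = extract_motif(dt, center).canonical_key
    return keys


# ---------------------------------------------------------------------------
# Graph assembly


def _sort_key(key: str) -> tuple:
    return (int(key.partition("|")[0]), key)


def build_flip_graph(
    distributions: list[MotifDistribution],
    edge_source: str = "combinatorial",
    empirical_edges: set | None = None,
    bfs_depth: int = 1,
    vertex_cap_factor: float = 10.0,
    bridge: bool = True,
) -> FlipGraph:
    """Flip graph over the union of observed motif supports.

    The vertex set starts from all observed canonical keys and is augmented by
    breadth-first flip expansion (combinatorial moves and/or harvested
    empirical transitions, per ``edge_source`` in {"combinatorial",
    "empirical", "union"}) up to ``bfs_depth`` shells, stopping early once the
    graph is connected and never exceeding ``vertex_cap_factor`` x the observed
    support size. If components remain, minimal bridge edges join them —
    pairing components through the motif pair with the smallest
    neighbor-count difference — and each bridge is reported as a warning.
    """
    if edge_source not in ("combinatorial", "empirical", "union"):
        raise InputError(f"unknown edge_source {edge_source!r}")
    use_comb = edge_source in ("combinatorial", "union")
    use_emp = edge_source in ("empirical", "union")
    if use_emp and not empirical_edges:
        if edge_source == "empirical":
            raise InputError("edge_source 'empirical' requires empirical_edges")
        empirical_edges = set()

    support = set()
    for d in distributions:
        support.update(d.counts)
    if not support:
        raise InputError("empty union of motif supports")
    observed = sorted(support, key=_sort_key)

    emp_adj: dict[str, set] = {}
    if use_emp:
        for a, b in empirical_edges or ():
            emp_adj.setdefault(a, set()).add(b)
            emp_adj.setdefault(b, set()).add(a)

    def neighbor_keys(key: str) -> tuple:
        out = flip_neighbor_keys(key) if use_comb else ()
        if use_emp and key in emp_adj:
            out = tuple(sorted(set(out) | emp_adj[key]))
        return out

    cap = max(len(observed), int(vertex_cap_factor * len(observed)))
    vertices = list(observed)
    present = set(vertices)
    adjacency: dict[str, tuple] = {}
    frontier = list(vertices)
    edge_pairs: set = set()

    def _current_components() -> tuple:
        idx = {k: i for i, k in enumerate(vertices)}
        rows, cols = [], []
        for a, b in edge_pairs:
            rows.append(idx[a])
            cols.append(idx[b])
        n = len(vertices)
        adj = sp.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        return connected_components(adj, directed=False)

    # Expansion shells are *added* at depths 1..bfs_depth but flip moves are
    # only enumerated for shells 0..bfs_depth-1: the outermost shell keeps the
    # edges to its discoverers (flip adjacency is symmetric) and any residual
    # disconnection is handled by bridging.
    for depth in range(bfs_depth + 1):
        if depth < bfs_depth or depth == 0:
            for v in frontier:
                if v not in adjacency:
                    adjacency[v] = neighbor_keys(v)
        edge_pairs = {
            (v, w) if v < w else (w, v)
            for v, nbrs in adjacency.items()
            for w in nbrs
            if w in present
        }
        n_comp, _ = _current_components()
        if n_comp == 1 or depth == bfs_depth:
            break
        discovered = {
            w for v in frontier for w in adjacency.get(v, ()) if w not in present
        }
        room = cap - len(vertices)
        if room <= 0 or not discovered:
            break
        new = sorted(discovered, key=_sort_key)[:room]
        vertices.extend(new)
        present.update(new)
        frontier = new

    n_comp, comp_ids = _current_components()

    index = {k: i for i, k in enumerate(vertices)}
    edges = sorted((index[a], index[b]) for a, b in edge_pairs)
    edges = [(min(e), max(e)) for e in edges]

    bridges: list = []
    if n_comp > 1 and bridge:
        # Pair components by the smallest neighbor-count difference: every
        # component is represented by its first vertex in (k, key) order;
        # components whose representatives share a neighbor count k attach in
        # a star to one per-k anchor (difference 0), and the anchors of
        # consecutive distinct k values are chained (minimal |dk|). Bridge
        # path lengths are therefore bounded by the neighbor-count range and
        # never grow with the number of observed motifs.
        order = sorted(range(len(vertices)), key=lambda i: _sort_key(vertices[i]))
        reps: dict[int, int] = {}
        for i in order:
            reps.setdefault(int(comp_ids[i]), i)
        buckets: dict[int, list] = {}
        for c, r in sorted(reps.items(), key=lambda cr: _sort_key(vertices[cr[1]])):
            k = int(vertices[r].partition("|")[0])
            buckets.setdefault(k, []).append(r)
        anchors = {k: members[0] for k, members in buckets.items()}
        for k, members in buckets.items():
            for r in members[1:]:
                a, b = anchors[k], r
                bridges.append((a, b) if a < b else (b, a))
        ks = sorted(anchors)
        for k1, k2 in zip(ks, ks[1:]):
            a, b = anchors[k1], anchors[k2]
            bridges.append((a, b) if a < b else (b, a))
        warnings.warn(
            f"flip graph disconnected: added {len(bridges)} bridge edges "
            f"joining {n_comp} components (star per neighbor count over "
            f"{len(ks)} counts, anchors chained across counts)",
            stacklevel=2,
        )
        edges = sorted(set(edges) | set(bridges))

    n = len(vertices)
    m = len(edges)
    if m:
        earr = np.asarray(edges, dtype=np.int64)
        rows = np.repeat(np.arange(m), 2)
        cols = earr.ravel()
        data = np.tile([1.0, -1.0], m)
        D = sp.csr_matrix((data, (rows, cols)), shape=(m, n))
    else:
        earr = np.zeros((0, 2), dtype=np.int64)
        D = sp.csr_matrix((0, n))
    L = (D.T @ D).tocsc()
    return FlipGraph(
        vertices=tuple(vertices),
        edges=earr,
        incidence=D,
        laplacian=L,
        component_ids=comp_ids,
        bridges=tuple(bridges),
    )


def graph_from_edges(vertices: list, edges: list) -> FlipGraph:
    """Assemble a :class:`FlipGraph` from an explicit vertex/edge list.

    Useful for analyses on abstract graphs (and for validating the distance
    operators against closed-form cases); ``edges`` are index pairs.
    """
    n = len(vertices)
    uniq = set()
    for i, j in edges:
        if i == j:
            raise InputError("self-loop edge")
        if not (0 <= i < n and 0 <= j < n):
            raise InputError("edge index out of range")
        uniq.add((i, j) if i < j else (j, i))
    edges = sorted(uniq)
    m = len(edges)
    if m:
        earr = np.asarray(edges, dtype=np.int64)
        rows = np.repeat(np.arange(m), 2)
        D = sp.csr_matrix(
            (np.tile([1.0, -1.0], m), (rows, earr.ravel())), shape=(m, n)
        )
    else:
        earr = np.zeros((0, 2), dtype=np.int64)
        D = sp.csr_matrix((0, n))
    L = (D.T @ D).tocsc()
    adj = sp.coo_matrix(
        (np.ones(m), (earr[:, 0], earr[:, 1])) if m else ((), ((), ())), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    return FlipGraph(
        vertices=tuple(vertices),
        edges=earr,
        incidence=D,
        laplacian=L,
        component_ids=comp,
    )


# ---------------------------------------------------------------------------
# Interchange


def write_flip_graph(graph: FlipGraph, path) -> None:
    """Edge list (as vertex indices) plus vertex table of canonical keys."""
    path = str(path)
    with open(path, "w") as fh:
        fh.write(f"# n_vertices: {graph.n_vertices}\n")
        fh.write(f"# bridges: {';'.join(f'{i}-{j}' for i, j in graph.bridges)}\n")
        fh.write("i,j\n")
        for i, j in graph.edges:
            fh.write(f"{i},{j}\n")
    with open(path + ".vertices", "w") as fh:
        fh.write("index,key\n")
        for i, k in enumerate(graph.vertices):
            fh.write(f"{i},{k}\n")


def read_flip_graph(path) -> FlipGraph:
    path = str(path)
    vertices = []
    with open(path + ".vertices") as fh:
        next(fh)
        for line in fh:
            _, key = line.strip().split(",", 1)
            vertices.append(key)
    bridges: tuple = ()
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "bridges:" in line:
                    raw = line.split("bridges:")[1].strip()
                    bridges = tuple(
                        tuple(int(x) for x in p.split("-")) for p in raw.split(";") if p
                    )
                continue
            if not line or line.startswith("i,"):
                continue
            i, j = line.split(",")
            edges.append((int(i), int(j)))
    n = len(vertices)
    m = len(edges)
    if m:
        earr = np.asarray(edges, dtype=np.int64)
        rows = np.repeat(np.arange(m), 2)
        D = sp.csr_matrix(
            (np.tile([1.0, -1.0], m), (rows, earr.ravel())), shape=(m, n)
        )
    else:
        earr = np.zeros((0, 2), dtype=np.int64)
        D = sp.csr_matrix((0, n))
    L = (D.T @ D).tocsc()
    adj = sp.coo_matrix(
        (np.ones(m), (earr[:, 0], earr[:, 1])) if m else ((), ((), ())), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    return FlipGraph(
        vertices=tuple(vertices),
        edges=earr,
        incidence=D,
        laplacian=L,
        component_ids=comp,
        bridges=bridges,
    )
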