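"""Neighborhood motifs and their empirical distributions.

The *motif* of a point is the simplicial complex spanned by the point and its
radius-1 Delaunay neighborhood: all tetrahedra whose vertices lie in
``{center} u N(center)``, where ``N(center)`` is the set of vertices sharing a
tetrahedron with the center. Motifs capture the local packing topology; a
cloud is summarized by the relative frequency of each distinct motif among its
bulk points.

Two motifs are the same if a relabeling of the neighbors (the center is
always vertex 0 and fixed) maps one tetrahedron set onto the other. Each
motif is therefore reduced to a *canonical key*: the lexicographically
minimal sorted tetrahedron list over all center-fixing relabelings,
computed by iterated color refinement plus individualization search —
exact, and fast because motifs are small (typically under 25 vertices).
The key serializes the full complex and round-trips losslessly; a
cryptographic digest of it is used as a compact identifier, but correctness
never depends on the hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
from fractions import Fraction
from functools import cached_property

import numpy as np

from .errors import InputError, NoBulkPointsError
from .tessellation import BulkMask, SimplicialComplex

__all__ = [
    "Motif",
    "MotifDistribution",
    "extract_motif",
    "canonical_label",
    "motif_from_key",
    "key_digest",
    "motif_distribution",
    "merge_distributions",
    "write_distribution",
    "read_distribution",
]


@dataclasses.dataclass(frozen=True)
class Motif:
    """A center's radius-1 neighborhood complex, center relabeled to 0."""

    n_neighbors: int
    tetrahedra: tuple  # tuple of sorted 4-tuples over {0..n_neighbors}
    source_vertices: tuple | None = None  # original cloud indices, center first

    def __post_init__(self) -> None:
        tets = tuple(sorted(tuple(sorted(t)) for t in self.tetrahedra))
        if not tets:
            raise InputError("motif must contain at least one tetrahedron")
        seen = set()
        for t in tets:
            if len(set(t)) != 4:
                raise InputError("tetrahedron with repeated vertex")
            if min(t) < 0 or max(t) > self.n_neighbors:
                raise InputError("motif vertex index out of range")
            if t in seen:
                raise InputError("duplicate tetrahedron")
            seen.add(t)
        covered = set().union(*(set(t) for t in tets))
        if covered != set(range(self.n_neighbors + 1)):
            raise InputError("every motif vertex must appear in a tetrahedron")
        object.__setattr__(self, "tetrahedra", tets)

    @cached_property
    def canonical_key(self) -> str:
        return canonical_label(self)

    @cached_property
    def digest(self) -> str:
        return key_digest(self.canonical_key)


# ---------------------------------------------------------------------------
# Canonical labeling


def _refine(colors: dict, adj: dict) -> dict:
    """Iterated 1-dimensional color refinement on the weighted 1-skeleton.

    ``colors`` maps neighbor vertex -> int, ``adj`` maps v -> {u: multiplicity}
    (multiplicity = number of shared tetrahedra; vertex 0 participates with a
    fixed sentinel color). Refines until the partition stabilizes; the integer
    order of colors is determined by sorting invariant signatures, so it is
    itself isomorphism-invariant.
    """
    colors = _normalize(colors)
    while True:
        sigs = {}
        for v, c in colors.items():
            nbr = sorted(
                (colors.get(u, -1), m) for u, m in adj[v].items()
            )  # color -1 = the fixed center
            sigs[v] = (c, tuple(nbr))
        palette = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
        new = {v: palette[s] for v, s in sigs.items()}
        if new == colors:
            return colors
        colors = new


def _normalize(colors: dict) -> dict:
    palette = {c: i for i, c in enumerate(sorted(set(colors.values())))}
    return {v: palette[c] for v, c in colors.items()}


def _serialize(n_neighbors: int, tets) -> str:
    body = ";".join(",".join(map(str, t)) for t in sorted(tets))
    return f"{n_neighbors}|{body}"


def canonical_label(motif: Motif) -> str:
    """Canonical key: minimal serialization over center-fixing relabelings."""
    k = motif.n_neighbors
    tets = motif.tetrahedra
    if k == 0:  # impossible for valid motifs, guarded by Motif invariants
        raise InputError("motif without neighbors")

    # weighted 1-skeleton restricted to neighbors (center enters via colors)
    adj: dict[int, dict[int, int]] = {v: {} for v in range(1, k + 1)}
    inc = {v: 0 for v in range(1, k + 1)}
    for t in tets:
        for v in t:
            if v:
                inc[v] += 1
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = t[i], t[j]
                if a == 0:
                    adj[b][0] = adj[b].get(0, 0) + 1
                else:
                    adj[a][b] = adj[a].get(b, 0) + 1
                    adj[b][a] = adj[b].get(a, 0) + 1

    init_sigs = {
        v: (
            len([u for u in adj[v] if u != 0]),
            adj[v].get(0, 0),
            inc[v],
        )
        for v in range(1, k + 1)
    }
    palette = {s: i for i, s in enumerate(sorted(set(init_sigs.values())))}
    colors = _refine({v: palette[s] for v, s in init_sigs.items()}, adj)

    best: list[str | None] = [None]

    def emit(colors: dict) -> None:
        order = sorted(colors, key=lambda v: colors[v])
        relabel = {0: 0}
        for i, v in enumerate(order, start=1):
            relabel[v] = i
        key = _serialize(k, (tuple(sorted(relabel[v] for v in t)) for t in tets))
        if best[0] is None or key < best[0]:
            best[0] = key

    def search(colors: dict) -> None:
        by_color: dict[int, list] = {}
        for v, c in colors.items():
            by_color.setdefault(c, []).append(v)
        target = None
        for c in sorted(by_color):
            if len(by_color[c]) > 1:
                target = by_color[c]
                break
        if target is None:
            emit(colors)
            return
        for v in target:
            search(_refine(_split_individualized(colors, v), adj))

    def _split_individualized(colors: dict, v: int) -> dict:
        # re-rank colors on a doubled scale so v can sit strictly below its class
        doubled = {u: 2 * c for u, c in colors.items()}
        doubled[v] = 2 * colors[v] - 1
        return _normalize(doubled)

    search(colors)
    assert best[0] is not None
    return best[0]


def key_digest(key: str) -> str:
    """Stable cryptographic digest of a canonical key."""
    return hashlib.sha1(key.encode()).hexdigest()


def motif_from_key(key: str) -> Motif:
    """Reconstruct a motif from its (or any valid) serialization."""
    head, _, body = key.partition("|")
    tets = tuple(
        tuple(int(x) for x in part.split(",")) for part in body.split(";")
    )
    return Motif(n_neighbors=int(head), tetrahedra=tets)


# ---------------------------------------------------------------------------
# Extraction from a tessellation


def extract_motif(dt: SimplicialComplex, center: int) -> Motif:
    """Radius-1 motif of ``center``: all tetrahedra inside its closed
    neighborhood, including tetrahedra among neighbors that do not contain the
    center itself."""
    incident = dt.vertex_tetrahedra[center]
    if incident.size == 0:
        raise InputError(f"no incident tetrahedra for vertex {center}")
    neighbors = np.unique(dt.tetrahedra[incident])
    neighbors = neighbors[neighbors != center]
    closed = set(int(v) for v in neighbors) | {int(center)}
    candidates = np.unique(
        np.concatenate([dt.vertex_tetrahedra[v] for v in neighbors])
    )
    rows = dt.tetrahedra[candidates]
    keep = np.all(np.isin(rows, np.fromiter(closed, int, len(closed))), axis=1)
    relabel = {int(center): 0}
    ordered = sorted(closed - {int(center)})
    for i, v in enumerate(ordered, start=1):
        relabel[v] = i
    tets = tuple(tuple(sorted(relabel[int(v)] for v in row)) for row in rows[keep])
    return Motif(
        n_neighbors=len(ordered),
        tetrahedra=tets,
        source_vertices=(int(center), *ordered),
    )


# ---------------------------------------------------------------------------
# Distributions


@dataclasses.dataclass(frozen=True)
class MotifDistribution:
    """Empirical probability over canonical motif keys for one sample."""

    counts: dict  # canonical key -> count (int, Fraction, or float)
    n_samples: int
    provenance: tuple = ()

    def __post_init__(self) -> None:
        if not self.counts:
            raise InputError("empty motif distribution")
        if self.n_samples <= 0:
            raise InputError("n_samples must be positive")
        if any(c <= 0 for c in self.counts.values()):
            raise InputError("all motif counts must be positive")

    @cached_property
    def weights(self) -> dict:
        total = sum(self.counts.values())
        return {k: v / total for k, v in self.counts.items()}

    @property
    def support(self) -> tuple:
        return tuple(sorted(self.counts))

    @property
    def label(self) -> str:
        return self.provenance[0] if self.provenance else "sample"


def motif_distribution(
    dt: SimplicialComplex,
    mask: BulkMask,
    exclusion: str = "touch",
    sample_id: str = "sample",
) -> MotifDistribution:
    """Empirical motif distribution over retained bulk centers.

    Exclusion policies:

    - ``"center"``: drop centers flagged as boundary;
    - ``"touch"`` (default): additionally drop centers whose neighborhood
      contains any boundary vertex, since their motifs are geometrically
      distorted by the missing exterior.
    """
    if exclusion not in ("center", "touch"):
        raise InputError(f"unknown exclusion policy {exclusion!r}")
    boundary = mask.is_boundary
    counts: dict[str, int] = {}
    n_used = 0
    for center in range(dt.n_vertices):
        if boundary[center]:
            continue
        incident = dt.vertex_tetrahedra[center]
        if incident.size == 0:
            continue
        if exclusion == "touch":
            neighborhood = np.unique(dt.tetrahedra[incident])
            if boundary[neighborhood].any():
                continue
        key = extract_motif(dt, center).canonical_key
        counts[key] = counts.get(key, 0) + 1
        n_used += 1
    if n_used == 0:
        raise NoBulkPointsError("no bulk points survive boundary exclusion")
    return MotifDistribution(counts=counts, n_samples=n_used, provenance=(sample_id,))


def merge_distributions(
    dists: list[MotifDistribution], weights: list[float] | None = None
) -> MotifDistribution:
    """Mixture of distributions, weighted by ``n_samples`` unless given.

    Exact arithmetic (rational weights) keeps merged frequencies lossless,
    e.g. when pooling sequential time points into one window.
    """
    if not dists:
        raise InputError("need at least one distribution to merge")
    if weights is None:
        w = [Fraction(d.n_samples) for d in dists]
    else:
        if len(weights) != len(dists):
            raise InputError("weights must match distributions")
        if any(x < 0 for x in weights) or sum(weights) <= 0:
            raise InputError("weights must be nonnegative with positive sum")
        w = [Fraction(x).limit_denominator(10**12) for x in weights]
    total_w = sum(w)
    mixed: dict[str, Fraction] = {}
    for d, wi in zip(dists, w):
        if wi == 0:
            continue
        for key, weight in d.weights.items():
            mixed[key] = mixed.get(key, Fraction(0)) + (wi / total_w) * Fraction(weight)
    n_total = sum(d.n_samples for d in dists)
    prov = tuple(p for d in dists for p in d.provenance)
    return MotifDistribution(counts=mixed, n_samples=n_total, provenance=prov)


# ---------------------------------------------------------------------------
# Interchange: digest,count table + sidecar digest -> canonical key map


def write_distribution(dist: MotifDistribution, path, comments: list[str] | None = None) -> None:
    path = str(path)
    keys = sorted(dist.counts)
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write(f"# n_samples: {dist.n_samples}\n")
        fh.write(f"# provenance: {';'.join(dist.provenance)}\n")
        fh.write("digest,count\n")
        for key in keys:
            c = dist.counts[key]
            if isinstance(c, Fraction):
                fh.write(f"{key_digest(key)},{c.numerator}/{c.denominator}\n")
            else:
                fh.write(f"{key_digest(key)},{c!r}\n")
    with open(path + ".keys", "w") as fh:
        fh.write("digest,key\n")
        for key in keys:
            fh.write(f"{key_digest(key)},{key}\n")


def read_distribution(path) -> MotifDistribution:
    path = str(path)
    digest_to_key = {}
    with open(path + ".keys") as fh:
        next(fh)
        for line in fh:
            digest, key = line.strip().split(",", 1)
            digest_to_key[digest] = key
    n_samples, provenance = 1, ()
    counts: dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "n_samples:" in line:
                    n_samples = int(line.split("n_samples:")[1].strip())
                elif "provenance:" in line:
                    raw = line.split("provenance:")[1].strip()
                    provenance = tuple(p for p in raw.split(";") if p)
                continue
            if not line or line.startswith("digest,"):
                continue
            digest, raw = line.split(",", 1)
            if "/" in raw:
                num, den = raw.split("/")
                value: object = Fraction(int(num), int(den))
            else:
                f = float(raw)
                value = int(f) if f.is_integer() else f
            counts[digest_to_key[digest]] = value
    return MotifDistribution(counts=counts, n_samples=n_samples, provenance=provenance)
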