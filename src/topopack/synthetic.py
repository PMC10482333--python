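"""Seeded generators for disordered point clouds.

Every pipeline stage is testable offline against clouds with known structure:

- ``poisson`` — uniform (ideal-gas) points in a box; the maximally
  disordered, memoryless reference.
- ``jittered_lattice`` — cubic or FCC crystal plus Gaussian jitter; ordered
  packing with tunable disorder.
- ``hard_sphere_rsa`` — random sequential addition of hard spheres; disordered
  but with a strict exclusion distance, as in granular/colloidal packings.
- ``dla`` — off-lattice diffusion-limited aggregation; strongly correlated,
  branched growth with long-range memory.
- ``relaxed_random`` — uniform points relaxed under soft repulsion; the
  liquid-like control.

:func:`randomize_and_relax` implements the growth-memory control: positions
are redrawn uniformly inside the alpha-shape of the original cloud
(destroying any correlation inherited from growth) and then relaxed by
overdamped dynamics under a soft pairwise repulsion, so that only the
short-range packing constraint is restored. Comparing a cloud against its
randomized-and-relaxed counterpart isolates the topological signature of the
growth process from that of mere steric packing. The relaxation model is
deliberately minimal — isotropic soft spheres with a linear-spring overlap
force — rather than any system-specific interaction model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, median_nn_distance
from .errors import InputError, SaturatedPackingError
from .tessellation import alpha_complex, build_delaunay, default_alpha

__all__ = ["GeneratorSpec", "generate", "randomize_and_relax"]

KINDS = ("poisson", "jittered_lattice", "hard_sphere_rsa", "dla", "relaxed_random")


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic cloud; identical spec -> identical cloud."""

    kind: str
    n: int = 1000
    seed: int = 0
    box: float = 1.0  # box edge length (poisson, RSA, relaxed_random)
    spacing: float = 1.0  # lattice constant
    jitter: float = 0.1  # lattice jitter, fraction of spacing
    lattice: str = "cubic"  # "cubic" | "fcc"
    radius: float = 0.02  # hard-sphere radius (RSA), units of box
    step_size: float = 0.2  # relaxation step (relaxed_random)
    n_steps: int = 50  # relaxation steps (relaxed_random)
    repulsion_range: float | None = None  # default: median NN distance

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InputError(f"unknown generator kind {self.kind!r}")
        if self.n < 1:
            raise InputError("n must be positive")
        for field in ("box", "spacing", "radius", "step_size"):
            if getattr(self, field) <= 0:
                raise InputError(f"{field} must be positive")
        if self.jitter < 0 or self.n_steps < 0:
            raise InputError("jitter and n_steps must be nonnegative")


def generate(spec: GeneratorSpec) -> PointCloud:
    """Generate the cloud described by ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    sample_id = f"{spec.kind}-{spec.seed}"
    if spec.kind == "poisson":
        coords = rng.uniform(0.0, spec.box, size=(spec.n, 3))
    elif spec.kind == "jittered_lattice":
        coords = _lattice(spec, rng)
    elif spec.kind == "hard_sphere_rsa":
        coords = _rsa(spec, rng)
    elif spec.kind == "dla":
        coords = _dla(spec, rng)
    elif spec.kind == "relaxed_random":
        coords = rng.uniform(0.0, spec.box, size=(spec.n, 3))
        rrange = spec.repulsion_range or 1.2 * median_nn_distance(coords)
        coords = _relax(
            coords, rrange, spec.step_size, spec.n_steps, bounds=(0.0, spec.box)
        )
    return PointCloud(
        coords=coords,
        sample_id=sample_id,
        group_label=spec.kind,
        rng_seed=spec.seed,
    )


def _lattice(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    side = int(np.ceil(spec.n ** (1 / 3)))
    g = np.arange(side) * spec.spacing
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    if spec.lattice == "fcc":
        offsets = (
            np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
            * spec.spacing
        )
        pts = (pts[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    elif spec.lattice != "cubic":
        raise InputError(f"unknown lattice {spec.lattice!r}")
    pts = pts[: spec.n] if len(pts) >= spec.n else pts
    if len(pts) < spec.n:
        raise InputError(f"lattice too small for n={spec.n}")
    if spec.jitter > 0:
        pts = pts + rng.normal(scale=spec.jitter * spec.spacing, size=pts.shape)
    return pts


def _rsa(spec: GeneratorSpec, rng: np.random.Generator, max_attempts: int = 200) -> np.ndarray:
    """Random sequential addition: reject candidates overlapping placed spheres."""
    placed: list[np.ndarray] = []
    tree: cKDTree | None = None
    min_dist = 2.0 * spec.radius
    attempts_since = 0
    while len(placed) < spec.n:
        cand = rng.uniform(0.0, spec.box, size=3)
        ok = True
        if placed:
            if tree is None or len(tree.data) < len(placed):
                tree = cKDTree(np.array(placed))
            d, _ = tree.query(cand)
            ok = d >= min_dist
        if ok:
            placed.append(cand)
            tree = None
            attempts_since = 0
        else:
            attempts_since += 1
            if attempts_since >= max_attempts * max(1, spec.n):
                raise SaturatedPackingError(
                    f"packing saturated at {len(placed)} < {spec.n}"
                )
    return np.array(placed)


def _dla(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Off-lattice diffusion-limited aggregation with unit-diameter particles.

    Walkers launch from a sphere just outside the cluster, take steps whose
    length adapts to the distance from the cluster (exact for the far field
    of Brownian motion up to first contact), stick on contact, and are
    relaunched if they wander past the kill radius.
    """
    diameter = 1.0
    pts = [np.zeros(3)]
    tree = cKDTree(np.array(pts))
    r_cluster = 0.0
    while len(pts) < spec.n:
        r_launch = r_cluster + 5.0 * diameter
        r_kill = r_launch * 3.0
        u = rng.normal(size=3)
        walker = r_launch * u / np.linalg.norm(u)
        while True:
            d, _ = tree.query(walker)
            if d < diameter:
                # back the walker up onto the contact sphere
                dn, j = tree.query(walker)
                contact = pts[j] + (walker - pts[j]) * (diameter / max(dn, 1e-12))
                pts.append(contact)
                r_cluster = max(r_cluster, float(np.linalg.norm(contact)))
                tree = cKDTree(np.array(pts))
                break
            step = max(d - diameter, 0.2 * diameter)
            u = rng.normal(size=3)
            walker = walker + step * u / np.linalg.norm(u)
            rw = float(np.linalg.norm(walker))
            if rw > r_kill:
                u = rng.normal(size=3)
                walker = r_launch * u / np.linalg.norm(u)
    return np.array(pts)


def _relax(
    coords: np.ndarray,
    repulsion_range: float,
    step_size: float,
    n_steps: int,
    bounds: tuple | None = None,
) -> np.ndarray:
    """Overdamped relaxation under a soft linear-spring overlap repulsion.

    Pairs closer than ``repulsion_range`` push apart with force proportional
    to their overlap; positions move by ``step_size`` times the net force per
    step and are clipped to ``bounds`` if given.
    """
    x = np.array(coords, dtype=float)
    for _ in range(n_steps):
        tree = cKDTree(x)
        pairs = tree.query_pairs(repulsion_range, output_type="ndarray")
        if pairs.size == 0:
            break
        diff = x[pairs[:, 0]] - x[pairs[:, 1]]
        dist = np.linalg.norm(diff, axis=1)
        dist = np.maximum(dist, 1e-12)
        overlap = repulsion_range - dist
        force = (overlap / dist)[:, None] * diff
        net = np.zeros_like(x)
        np.add.at(net, pairs[:, 0], force)
        np.add.at(net, pairs[:, 1], -force)
        x += step_size * net
        if bounds is not None:
            x = np.clip(x, bounds[0], bounds[1])
    return x


def randomize_and_relax(
    cloud: PointCloud,
    repulsion_range: float | None = None,
    step_size: float = 0.2,
    n_steps: int = 50,
    seed: int = 0,
    alpha: float | None = None,
) -> PointCloud:
    """Growth-memory control: redraw positions in the cloud's alpha-shape,
    then relax under soft repulsion.

    Redrawing uniformly inside the alpha-shape destroys all positional
    correlations inherited from the growth history while preserving the
    overall shape and density; the subsequent overdamped soft-sphere
    relaxation restores only the short-range packing constraint. ``n_steps=0``
    returns the bare uniform redraw.
    """
    if cloud.n < 5:
        raise InputError("need >= 5 points")
    rng = np.random.default_rng(seed)
    dt = build_delaunay(cloud)
    pts = dt.points if dt.points is not None else cloud.coords
    if alpha is None:
        alpha = default_alpha(cloud)
    ac = alpha_complex(dt, cloud, alpha)
    tets = ac.tetrahedra if ac.n_tetrahedra else dt.tetrahedra
    # sample uniformly over tetrahedra, weighted by volume
    corners = pts[tets]
    vol = np.abs(
        np.einsum(
            "ij,ij->i",
            np.cross(corners[:, 1] - corners[:, 0], corners[:, 2] - corners[:, 0]),
            corners[:, 3] - corners[:, 0],
        )
    )
    prob = vol / vol.sum()
    chosen = rng.choice(len(tets), size=cloud.n, p=prob)
    # uniform barycentric coordinates via sorted-uniform spacings
    u = np.sort(rng.uniform(size=(cloud.n, 3)), axis=1)
    bary = np.column_stack([u[:, 0], u[:, 1] - u[:, 0], u[:, 2] - u[:, 1], 1 - u[:, 2]])
    new = np.einsum("nk,nkd->nd", bary, corners[chosen])
    if repulsion_range is None:
        repulsion_range = median_nn_distance(pts)
    if n_steps > 0:
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        new = _relax(new, repulsion_range, step_size, n_steps, bounds=(lo, hi))
    return cloud.with_coords(
        new, sample_id=f"{cloud.sample_id}-randomized", rng_seed=seed
    )
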