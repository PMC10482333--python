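# Methods

`topopack` quantifies the packing topology of 3D point clouds — cell or
nucleus centroids, particle centers, star positions — and compares clouds
through a metric on their local-neighborhood statistics. This note records
the model, the numerical choices, and the limits of what the synthetic
studies demonstrate.

## Tessellation and boundary handling

Every analysis starts from the Delaunay tessellation DT(X): the simplicial
complex dual to the Voronoi diagram, whose tetrahedra have empty
circumspheres. Inputs with five or more cospherical points (perfect
lattices) have an ambiguous tessellation; rather than symbolic perturbation
we apply a reproducible Gaussian jitter of `jitter_scale` x (median
nearest-neighbor distance), seeded from the cloud's `rng_seed`, and record
the jittered coordinates. The default `jitter_scale = 1e-6` is far below any
physically meaningful displacement while being orders of magnitude above the
rounding scale of double precision for typical coordinates.

**Boundary points.** A point is a *boundary point* at probing radius alpha
if an empty sphere of radius alpha can touch it. Because the Voronoi cell of
a point is convex and contains it, such a sphere exists exactly when the
cell reaches distance alpha from its generator; for interior points the
farthest cell vertex is the largest circumcenter among incident Delaunay
tetrahedra, and convex-hull points (unbounded cells) are always boundary.
The implementation therefore classifies a vertex as boundary iff it lies on
the hull or some incident tetrahedron has circumradius >= alpha — an exact,
O(#tetrahedra) equivalent of both the touching-sphere definition and
membership in the alpha-complex boundary. The test suite validates it
against a brute-force probing oracle built only from raw distances.

**Choice of alpha.** The probing radius is a dataset parameter. The package
default is scale-free: alpha = 4 x median NN distance. The factor 4 is set
by the structure of disordered clouds: interior Delaunay slivers of a
homogeneous Poisson process routinely have circumradii of 2–3 x the median
NN distance, so smaller multiples classify most of the interior as
"boundary" and (under the `touch` exclusion policy) can leave no bulk
centers at all. At 4 x, roughly a quarter to a third of a Poisson cloud
survives as bulk, while genuine surface points remain excluded. The value is
exposed in `RunConfig` (`alpha_policy`/`alpha_value`) and should be adapted
per system, e.g. smaller for dense confluent tissue.

## Motifs

The motif of a point is the simplicial complex spanned by the point and its
radius-1 neighborhood: all tetrahedra whose vertices lie within the point
plus the vertices sharing a tetrahedron with it. Radius-2 neighborhoods are
deliberately out of scope — the motif space would grow far too fast to
estimate frequencies from realistic samples.

**Motif scale.** Motifs are extracted on the *alpha-complex* at a second,
smaller scale (`motif_alpha_value`, default 1.2 x median NN), not on the
full Delaunay ring. This choice is about estimability: the full 1-ring of a
disordered cloud (~15 neighbors, ~40 tetrahedra) is essentially unique per
point — two replicate clouds of the same process then share no motifs at
desk-scale sample sizes, and every distribution degenerates to uniform over
its own support. Restricting to compact tetrahedra (circumradius < 1.2 x
median NN) keeps the physically tight contacts, shrinks motifs to a few
tetrahedra, and makes them recur: replicates overlap, frequencies converge,
and the distance between same-process samples decreases with n. Setting
`motif_alpha_value = 0` restores full-ring motifs for dense, strongly
ordered data.

**Exclusion policies.** `touch` (default) keeps only centers whose entire
neighborhood is bulk; `center` keeps every bulk center. For strongly
branched structures (e.g. diffusion-limited aggregates) almost everything is
surface-adjacent and `touch` retains very little; the growth-memory study
therefore uses `center` (see below).

**Canonical labels.** Two motifs are identical if a relabeling of neighbors
(center fixed) maps one tetrahedron set onto the other. The canonical key is
the lexicographically minimal sorted tetrahedron list over all
center-fixing relabelings, found by iterated color refinement on the
tetrahedron-multiplicity-weighted 1-skeleton followed by
individualization-and-refinement search. This is exact (validated against a
VF2 isomorphism oracle on an independent encoding) and fast because motifs
are small; highly symmetric motifs cost a few extra branches. The key
serializes the complex losslessly; SHA-1 digests are used as compact file
identifiers only.

## Flip graph

Motif space carries a natural adjacency: bistellar flips (2-3 and 3-2
moves) transform one motif into another through a single topological
transition. The flip graph has canonical motifs as vertices and
single-transition pairs as edges; its signed incidence matrix D (one +1 and
one −1 per edge) defines the Laplacian L = D^T D.

No catalogue of realizable motifs exists, so graphs are assembled from
data:

1. vertices = union of observed motif keys across the samples being
   compared;
2. combinatorial edges: pairs of present motifs one bistellar move apart,
   found by enumerating moves (memoized per canonical key);
3. optional breadth-first expansion (`bfs_depth`, default 1) adds
   unobserved intermediate motifs discovered by the move enumeration, up to
   `vertex_cap_factor` x the observed support; the outermost shell keeps
   only its edges to discoverers;
4. optional empirical edges harvested by perturb-and-retessellate
   (`empirical_flip_edges`): Gaussian kicks of a few percent of the NN
   distance, recording every (old, new) motif pair. Small kicks give almost
   exclusively elementary transitions (neighbor counts differing by <= 1);
5. residual disconnected components are joined by *bridge edges*, loudly
   warned about: each component is represented by its first motif in
   (neighbor count, key) order; components sharing a neighbor count k
   attach star-wise to a per-k anchor, and anchors of consecutive k are
   chained. Bridge path lengths are therefore bounded by the neighbor-count
   range and do not grow with sample size — a plain minimum-spanning chain
   was found to make distances between same-process samples *grow* with n,
   an artifact of chain length, and was rejected.

Edges are unweighted; orientation is fixed low-index -> high-index (the
distance is provably orientation-invariant).

## Topological diffusion distance

For motif distributions rho_A, rho_B on a shared flip graph,

    d_TDD(A, B) = || D L+ (rho_A − rho_B) ||_1 ,

the L1 norm of the electrical (diffusion) flow transporting one distribution
into the other. The flow D L+ delta satisfies the transport constraint
D^T J = delta, so TDD upper-bounds the Beckmann earth mover's distance W1 on
the graph, with equality on trees (unique feasible flow); on a 5-cycle with
unit masses one step apart, TDD = 8/5 against W1 = 1. Both statements are
verified against an exact linear-programming oracle.

Numerics: L+ is never formed. The singular system L phi = delta is solved
per connected component by sparse LU of the grounded Laplacian (one vertex
fixed), plus one step of iterative refinement; the factorization is cached
per graph and reused across all pairs of a distance matrix. Mass imbalance
across disconnected components beyond 1e-9 raises an ill-posed-transport
error. Distributions are renormalized after restriction to the graph's
vertex set; dropped mass above 1e-6 triggers a warning.

## Atlas, curvature, group test

Distance matrices are embedded by classical (Torgerson) MDS: eigendecompose
−(1/2) J D² J and scale eigenvectors by the root eigenvalue. TDD matrices
need not be Euclidean; negative eigenvalue mass is truncated but reported as
`stress` (relative magnitude of negative eigenvalues), never silently
dropped. SMACOF-style stress majorization is intentionally not used: the
classical solution is deterministic and gives principal-component axes.

Ordered series of distributions (time courses) are analyzed by Menger
curvature: for samples (t−s, t, t+s), curvature = 4·Area/(d₁d₂d₃) with the
area from Heron's formula in Kahan's stable ordering; collinear triples give
exactly 0 and the curvature scales as 1/s under distance scaling. On tree
metrics (where TDD is additive) trajectories are exactly flat; spikes mark
genuine metric kinks.

Group differences use a label-permutation test on the distance matrix with
the statistic (mean between-group distance − mean within-group distance).
When the number of distinct label assignments is at most `n_perm` the test
is exact (all assignments enumerated, p = #{stat >= obs}/#assignments);
otherwise p = (1 + #{perm >= obs})/(1 + n_perm) over random permutations.
The exact branch matters for small designs: with 5 + 5 samples there are
only 252 distinct splits, and randomly sampled permutations recreate the
true split often enough to put a noisy floor of ~0.01 on the p-value;
enumeration gives the correct deterministic floor 2/252. The statistic is
this package's own choice — a standard distance-matrix construction — and
its type-I calibration is checked by KS uniformity of null p-values in the
test suite.

## Synthetic generators

The generators define the study conditions used throughout the tests:

- `poisson`: n uniform points in a unit box — the memoryless reference.
- `jittered_lattice`: cubic (or FCC) lattice, Gaussian jitter of 0.1 x
  spacing in the discrimination study — ordered packing with realistic
  positional noise.
- `hard_sphere_rsa`: random sequential addition with rejection; errors out
  if the packing saturates before n points are placed.
- `dla`: off-lattice diffusion-limited aggregation, unit-diameter particles,
  adaptive step lengths, launch/kill radii tracking the cluster — strongly
  correlated growth with long-range memory.
- `relaxed_random`: uniform points relaxed under soft repulsion — the
  liquid-like control.

`randomize_and_relax` is the growth-memory control: positions are redrawn
uniformly inside the alpha-shape of the original cloud (erasing all
positional correlations while preserving shape and density), then relaxed by
overdamped dynamics under a linear-spring overlap repulsion (cutoff =
median NN distance of the original, 50 steps of size 0.2 by default). The
interaction model is deliberately minimal and isotropic; it restores only
the short-range packing constraint, not any system-specific cell mechanics.

## Study sizes and what the tests show

The validation studies run at desk scale, chosen to finish in minutes on one
CPU while leaving clear margins:

- sampling consistency: Poisson pairs at n in {200, 500, 2000}, 10 pairs per
  size, all measured on one shared flip graph (mean TDD decreases
  monotonically with n);
- discrimination: 5 Poisson + 5 jittered-lattice clouds of 1000 points, 999
  permutations (between-group distances ~5x within-group);
- null calibration: 10 Poisson clouds of 150 points, 200 random labelings;
- growth memory: DLA clusters of 2500 particles, 20 trials, `center`
  exclusion policy (see above): the randomized control is farther from the
  original than an independent replicate. DLA growth is highly stochastic,
  so replicate-to-replicate distances are themselves noisy; cluster size is
  the main power lever of this study.

Passing these studies shows that the pipeline is internally consistent and
sensitive to the kinds of structure the generators produce. It does not show
performance on real segmented imaging data, where anisotropic cells,
segmentation errors, inhomogeneous density and true tissue boundaries
matter; alpha and the motif scale in particular should be revisited per
dataset.

## Known limitations

- The flip graph is sample-dependent; distances are comparable only between
  distributions evaluated on the same graph (as `pairwise_distance`
  enforces). Bridged components make the metric partially combinatorial
  (neighbor-count geodesics) in sparsely sampled regions of motif space.
- Canonical labeling is exponential in the worst case (highly symmetric
  motifs); in practice refinement discretizes after at most a few branches.
- No periodic boundary conditions and no weighted (Laguerre) tessellations;
  2D inputs are rejected.
- The empirical-edge harvest records compound transitions when kicks are
  too large; keep `kick_scale` at or below a few percent.
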