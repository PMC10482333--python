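# topopack

Topological packing statistics for 3D point clouds.

Disordered packings are everywhere in the life sciences and beyond: nuclei
in a tissue, bacteria in a biofilm, particles in a colloid, stars in a
catalogue. Comparing the *structure* of such systems across scales and
imaging modalities is hard because coordinates, units and densities are
incommensurable. `topopack` compares them through topology alone:

1. **Tessellate.** Build the Delaunay tessellation DT(X) of the cloud
   (dual to the Voronoi diagram; tetrahedra with empty circumspheres), and
   classify boundary points — those an empty sphere of radius α can touch —
   via the α-complex.
2. **Count motifs.** For every bulk point, extract its *motif*: the
   simplicial complex of Delaunay tetrahedra spanned by the point and its
   radius-1 neighborhood, reduced to a canonical label invariant under
   relabeling. The cloud becomes an empirical probability distribution ρ
   over canonical motifs.
3. **Measure distances.** Motifs change only through discrete bistellar
   flips, which organizes motif space into a *flip graph* with incidence
   matrix D and Laplacian L = DᵀD. Two clouds are compared by the
   topological diffusion distance

       d_TDD(A, B) = ‖ D L⁺ (ρ_A − ρ_B) ‖₁ ,

   the total electrical flow transporting one motif distribution into the
   other. It relaxes the graph earth mover's distance W1 (TDD ≥ W1, with
   equality on trees) and is computed by sparse Laplacian solves, never by a
   dense pseudo-inverse.
4. **Build atlases.** Collections of clouds are embedded by classical MDS of
   the pairwise TDD matrix; ordered series get Menger-curvature trajectory
   analysis; group differences are tested by label permutation.

Everything runs offline on synthetic or user-supplied clouds; readers and
writers use plain delimited text (plus an optional HDF5 bundle for
multi-sample studies).

## Worked example

```python
import topopack as tp

cfg = tp.RunConfig()  # alpha = 4 x median NN, motif scale 1.2 x, "touch" exclusion

# two replicates of a random (Poisson) cloud and two jittered crystals
clouds = [
    tp.generate(tp.GeneratorSpec(kind="poisson", n=1000, seed=s)) for s in (1, 2)
] + [
    tp.generate(tp.GeneratorSpec(kind="jittered_lattice", n=1000, jitter=0.1, seed=s))
    for s in (1, 2)
]

dists = [tp.cloud_distribution(c, cfg) for c in clouds]
for d in dists:
    print(d.label, d.n_samples, len(d.counts))

dm = tp.pairwise_distance(dists)
print(dm.values.round(2))
```

Output:

```
poisson-1 377 139
poisson-2 344 124
jittered_lattice-1 222 222
jittered_lattice-2 221 221
[[ 0.    1.28 12.49 12.44]
 [ 1.28  0.   12.62 12.57]
 [12.49 12.62  0.    2.97]
 [12.44 12.57  2.97  0.  ]]
```

Each Poisson cloud keeps a few hundred bulk centers carrying ~130 distinct
motifs. The distance matrix shows the structure directly: replicates of the
same process sit at TDD ≈ 1.3–3.0 (sampling noise), while random and
crystalline packings are ≈ 12.5 apart — the block structure that MDS turns
into separated clusters in the atlas.

The same pipeline from the shell:

```bash
topopack simulate --kind poisson --n 1000 --seed 1 --out p1.csv
topopack simulate --kind jittered_lattice --n 1000 --seed 1 --out l1.csv
topopack distance p1.csv l1.csv --out dm.csv
topopack atlas dm.csv --out embedding.csv --plot atlas.png
topopack test-groups dm.csv --labels auto --out groups.csv
```

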