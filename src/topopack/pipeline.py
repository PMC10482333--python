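"""High-level pipeline helpers shared by the CLI and scripts.

These functions glue the stages together under a single :class:`RunConfig`:
cloud -> tessellation + boundary mask -> motif distribution -> shared flip
graph -> distance matrix -> atlas.
"""

from __future__ import annotations

from .cloud import PointCloud
from .config import RunConfig
from .distance import DistanceMatrix, pairwise_distance
from .motifs import MotifDistribution, motif_distribution
from .tessellation import (
    BulkMask,
    SimplicialComplex,
    alpha_complex,
    build_delaunay,
    classify_boundary,
    default_alpha,
)

__all__ = ["resolve_alpha", "tessellate_cloud", "cloud_distribution", "clouds_to_matrix"]


def resolve_alpha(cloud: PointCloud, config: RunConfig) -> float:
    if config.alpha_policy == "absolute":
        return config.alpha_value
    return default_alpha(cloud, multiple=config.alpha_value)


def tessellate_cloud(
    cloud: PointCloud, config: RunConfig
) -> tuple[SimplicialComplex, BulkMask, float]:
    alpha = resolve_alpha(cloud, config)
    dt = build_delaunay(cloud, jitter_scale=config.jitter_scale)
    mask = classify_boundary(dt, cloud, alpha)
    return dt, mask, alpha

def cloud_distribution(cloud: PointCloud, config: RunConfig) -> MotifDistribution:
    """Motif distribution of a cloud under the configured pipeline.

    Boundary exclusion uses the (large) probing scale ``alpha_value``; motifs
    themselves are extracted on the alpha-complex at the (small) scale
    ``motif_alpha_value``, which prunes oversized interior tetrahedra and
    makes motifs repeatable across samples of the same process. Setting
    ``motif_alpha_value = 0`` extracts motifs on the full Delaunay ring.
    """
    dt, mask, _ = tessellate_cloud(cloud, config)
    complex_for_motifs = dt
    if config.motif_alpha_value > 0:
        from .cloud import median_nn_distance

        pts = dt.points if dt.points is not None else cloud.coords
        motif_alpha = config.motif_alpha_value * median_nn_distance(pts)
        complex_for_motifs = alpha_complex(dt, cloud, motif_alpha)
    return motif_distribution(
        complex_for_motifs, mask, exclusion=config.exclusion, sample_id=cloud.sample_id
    )


def clouds_to_matrix(
    clouds: list[PointCloud], config: RunConfig, n_kicks: int = 5
) -> DistanceMatrix:
    dists = [cloud_distribution(c, config) for c in clouds]
    empirical = None
    if config.edge_source in ("empirical", "union"):
        from .flipgraph import empirical_flip_edges

        empirical = set()
        for i, cloud in enumerate(clouds):
            empirical |= empirical_flip_edges(
                cloud, n_kicks=n_kicks, seed=config.seed + i
            )
    return pairwise_distance(
        dists,
        method=config.distance_method,
        bfs_depth=config.bfs_depth,
        vertex_cap_factor=config.vertex_cap_factor,
        edge_source=config.edge_source,
        empirical_edges=empirical,
    )
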