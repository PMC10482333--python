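"""Run configuration: one object holding every pipeline default.

Serialized as a flat YAML key-value file; the SHA-1 digest of the canonical
serialization is embedded in every output file so results can always be traced
back to the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib

import yaml

from .errors import InputError

__all__ = ["RunConfig"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    #: "multiple": alpha = alpha_value x median NN distance (scale-free);
    #: "absolute": alpha = alpha_value in coordinate units.
    alpha_policy: str = "multiple"
    alpha_value: float = 4.0
    #: scale of the alpha-complex on which motifs are extracted, as a multiple
    #: of the median NN distance; 0 means motifs on the full Delaunay ring
    motif_alpha_value: float = 1.2
    #: degeneracy-resolving jitter, fraction of median NN distance
    jitter_scale: float = 1e-6
    #: boundary exclusion: "center" or "touch"
    exclusion: str = "touch"
    #: flip-graph edges: "combinatorial", "empirical" or "union"
    edge_source: str = "combinatorial"
    bfs_depth: int = 1
    vertex_cap_factor: float = 10.0
    distance_method: str = "TDD"
    mds_dim: int = 2
    n_perm: int = 999
    seed: int = 0
    #: "quiet", "info" or "debug"
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.alpha_policy not in ("multiple", "absolute"):
            raise InputError(f"unknown alpha_policy {self.alpha_policy!r}")
        if self.alpha_value <= 0:
            raise InputError("alpha_value must be positive")
        if self.motif_alpha_value < 0:
            raise InputError("motif_alpha_value must be >= 0")
        if self.exclusion not in ("center", "touch"):
            raise InputError(f"unknown exclusion {self.exclusion!r}")
        if self.edge_source not in ("combinatorial", "empirical", "union"):
            raise InputError(f"unknown edge_source {self.edge_source!r}")
        if self.distance_method not in ("TDD", "W1"):
            raise InputError(f"unknown distance_method {self.distance_method!r}")
        if self.verbosity not in ("quiet", "info", "debug"):
            raise InputError(f"unknown verbosity {self.verbosity!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @property
    def digest(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]
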