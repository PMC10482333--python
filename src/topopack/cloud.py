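"""Point clouds: the universal input.

A :class:`PointCloud` is an ``n x 3`` array of coordinates (length units are
arbitrary but must be consistent within a cloud) plus light metadata: a sample
identifier, an optional group label, and the RNG seed when the cloud was
generated synthetically.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "PointCloud",
    "median_nn_distance",
    "read_point_table",
    "write_point_table",
    "read_cloud_bundle",
    "write_cloud_bundle",
]


@dataclasses.dataclass(frozen=True)
class PointCloud:
    """An unordered set of points in 3D with provenance metadata."""

    coords: np.ndarray
    sample_id: str = "cloud"
    group_label: str | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(
                f"coordinates must be an (n, 3) array, got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n

    def with_coords(self, coords: np.ndarray, **meta) -> "PointCloud":
        """A copy with replaced coordinates (metadata preserved unless given)."""
        fields = dict(
            sample_id=self.sample_id,
            group_label=self.group_label,
            rng_seed=self.rng_seed,
        )
        fields.update(meta)
        return PointCloud(coords=coords, **fields)


def median_nn_distance(coords: np.ndarray) -> float:
    """Median nearest-neighbor distance; the cloud's intrinsic length scale.

    Used to make jitter magnitudes, kick sizes and the default boundary scale
    alpha dimensionless multiples of the local packing scale.
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise InputError("need at least 2 points for a nearest-neighbor scale")
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return float(np.median(d[:, 1]))


# ---------------------------------------------------------------------------
# Delimited-text interchange


def write_point_table(cloud: PointCloud, path, comments: list[str] | None = None) -> None:
    """Write a cloud as a delimited table with header ``x,y,z[,sample,group]``."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        if cloud.rng_seed is not None:
            fh.write(f"# rng_seed: {cloud.rng_seed}\n")
        cols = ["x", "y", "z", "sample"]
        if cloud.group_label is not None:
            cols.append("group")
        fh.write(",".join(cols) + "\n")
        for row in cloud.coords:
            fields = [f"{v:.17g}" for v in row] + [cloud.sample_id]
            if cloud.group_label is not None:
                fields.append(cloud.group_label)
            fh.write(",".join(fields) + "\n")


def read_point_table(path) -> list[PointCloud]:
    """Read one or more clouds from a delimited table.

    Columns ``x, y, z`` are required; optional ``sample`` splits rows into
    separate clouds and optional ``group`` attaches a group label.
    """
    seed = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "rng_seed:" in line:
                    try:
                        seed = int(line.split("rng_seed:")[1].strip())
                    except ValueError:
                        pass
            else:
                break
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise InputError(f"point table {path} is missing required column {col!r}")
    clouds = []
    if "sample" in df.columns:
        groups = df.groupby("sample", sort=True)
    else:
        groups = [("cloud", df)]
    for sample_id, sub in groups:
        group = None
        if "group" in sub.columns and not sub["group"].isna().all():
            group = str(sub["group"].iloc[0])
        clouds.append(
            PointCloud(
                coords=sub[["x", "y", "z"]].to_numpy(dtype=float),
                sample_id=str(sample_id),
                group_label=group,
                rng_seed=seed,
            )
        )
    return clouds


# ---------------------------------------------------------------------------
# HDF5 bundles for multi-sample studies


def write_cloud_bundle(clouds: Iterator[PointCloud], path) -> None:
    """Write several clouds into one HDF5 container (one dataset per sample)."""
    import h5py

    with h5py.File(path, "w") as fh:
        grp = fh.create_group("clouds")
        for cloud in clouds:
            ds = grp.create_dataset(cloud.sample_id, data=cloud.coords)
            if cloud.group_label is not None:
                ds.attrs["group"] = cloud.group_label
            if cloud.rng_seed is not None:
                ds.attrs["rng_seed"] = cloud.rng_seed


def read_cloud_bundle(path) -> list[PointCloud]:
    import h5py

    clouds = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh["clouds"]):
            ds = fh["clouds"][name]
            clouds.append(
                PointCloud(
                    coords=ds[()],
                    sample_id=name,
                    group_label=ds.attrs.get("group"),
                    rng_seed=int(ds.attrs["rng_seed"]) if "rng_seed" in ds.attrs else None,
                )
            )
    return clouds
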