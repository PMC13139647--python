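"""Regular cubic voxel grids over subplot point clouds.

A subplot cloud is discretised onto a grid of cubic voxels (default
edge 0.40 m). A voxel is *occupied* when it contains at least
``min_points`` returns (default 1: any return fills the voxel, the
binary occupied/empty model standard in TLS canopy work). Horizontal
layers of the grid carry an occupancy fraction with the constant
denominator ``nx * ny``, which is what the 10%-occupancy canopy
boundary is evaluated on.

Grid dimensions are derived from the subplot footprint and the cloud's
maximum height: ``n = ceil(extent / edge)`` per axis, so edge voxels may
overhang the footprint but every layer has the same voxel count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .pointcloud import PointCloud

__all__ = [
    "GridSpec",
    "VoxelGrid",
    "LayerProfile",
    "voxelize",
    "layer_profile",
    "occupied_in_slab",
    "spec_for_footprint",
    "write_grid_csv",
    "write_profile_csv",
]

DEFAULT_EDGE = 0.40


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid: origin (m), cubic edge length (m),
    voxel counts per axis, and the occupancy threshold in points."""

    origin: tuple[float, float, float]
    edge: float = DEFAULT_EDGE
    shape: tuple[int, int, int] = (1, 1, 1)
    min_points: int = 1

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("edge length must be positive")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError("grid shape must be >= 1 on every axis")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")

    @property
    def nx(self) -> int:
        return self.shape[0]

    @property
    def ny(self) -> int:
        return self.shape[1]

    @property
    def nz(self) -> int:
        return self.shape[2]

    def layer_z(self, k: int) -> tuple[float, float]:
        """[z_lo, z_hi) extent of horizontal layer ``k`` (bottom = 0)."""
        z0 = self.origin[2]
        return (z0 + k * self.edge, z0 + (k + 1) * self.edge)

    def layer_centre(self, k: int) -> float:
        return self.origin[2] + (k + 0.5) * self.edge


@dataclass(frozen=True)
class VoxelGrid:
    """Per-voxel point counts on a :class:`GridSpec`.

    ``counts`` has shape (nx, ny, nz); ``n_out_of_bounds`` tallies the
    points that fell outside the grid extent and were dropped.
    """

    spec: GridSpec
    counts: np.ndarray
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        if tuple(self.counts.shape) != self.spec.shape:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match spec {self.spec.shape}"
            )

    @property
    def occupied(self) -> np.ndarray:
        """Boolean occupancy array: count >= min_points."""
        return self.counts >= self.spec.min_points

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())


@dataclass(frozen=True)
class LayerProfile:
    """Occupancy fraction per horizontal layer (bottom layer first).

    ``occupancy[k]`` = occupied voxels in layer k / (nx * ny).
    """

    spec: GridSpec
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if self.occupancy.shape != (self.spec.nz,):
            raise ValueError("profile must have exactly nz entries")


def spec_for_footprint(
    footprint_x: float,
    footprint_y: float,
    max_z: float,
    edge: float = DEFAULT_EDGE,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    min_points: int = 1,
) -> GridSpec:
    """Derive a grid spec from a subplot footprint and canopy height.

    ``n = ceil(extent / edge)`` per axis (at least 1), so the grid covers
    the footprint entirely; the per-layer denominator stays nx * ny.
    """
    if footprint_x <= 0 or footprint_y <= 0:
        raise ValueError("footprint must be positive")
    nx = max(1, int(np.ceil(footprint_x / edge - 1e-9)))
    ny = max(1, int(np.ceil(footprint_y / edge - 1e-9)))
    nz = max(1, int(np.ceil(max_z / edge - 1e-9))) if max_z > 0 else 1
    return GridSpec(origin=origin, edge=edge, shape=(nx, ny, nz), min_points=min_points)


def voxelize(cloud: PointCloud, spec: GridSpec) -> VoxelGrid:
    """Count points per voxel.

    A point p maps to cell ``floor((p - origin) / edge)`` per axis.
    Points outside ``[origin, origin + shape * edge)`` on any axis are
    dropped and tallied in ``n_out_of_bounds`` (never an error: upstream
    clipping should make them rare). An empty cloud yields an all-zero
    grid.
    """
    counts = np.zeros(spec.shape, dtype=np.int64)
    if cloud.is_empty:
        return VoxelGrid(spec, counts, 0)
    rel = (cloud.xyz - np.asarray(spec.origin)) / spec.edge
    idx = np.floor(rel).astype(np.int64)
    shape = np.asarray(spec.shape)
    in_bounds = np.all((idx >= 0) & (idx < shape), axis=1)
    # guard against float edge cases: a point exactly at the upper face
    # belongs outside (half-open convention), which floor already gives
    kept = idx[in_bounds]
    np.add.at(counts, (kept[:, 0], kept[:, 1], kept[:, 2]), 1)
    return VoxelGrid(spec, counts, int((~in_bounds).sum()))


def layer_profile(grid: VoxelGrid) -> LayerProfile:
    """Occupancy fraction of every horizontal layer, denominator nx*ny."""
    footprint = grid.spec.nx * grid.spec.ny
    occ = grid.occupied.sum(axis=(0, 1)) / footprint
    return LayerProfile(grid.spec, occ.astype(float))


def occupied_in_slab(grid: VoxelGrid, layers: range) -> tuple[int, int]:
    """(occupied, total) voxel counts over a contiguous layer range.

    ``total`` is ``len(layers) * nx * ny``; the range must be non-empty
    and lie within [0, nz).
    """
    if len(layers) == 0:
        raise ValueError("layer range is empty")
    if layers.step != 1:
        raise ValueError("layer range must be contiguous (step 1)")
    if layers.start < 0 or layers.stop > grid.spec.nz:
        raise ValueError(
            f"layer range [{layers.start}, {layers.stop}) outside grid [0, {grid.spec.nz})"
        )
    occ = int(grid.occupied[:, :, layers.start : layers.stop].sum())
    total = len(layers) * grid.spec.nx * grid.spec.ny
    return occ, total


def write_grid_csv(grid: VoxelGrid, path: Union[str, Path]) -> None:
    """Export nonzero cells as (i, j, k, count) rows."""
    i, j, k = np.nonzero(grid.counts)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "k", "count"])
        for a, b, c in zip(i, j, k):
            w.writerow([int(a), int(b), int(c), int(grid.counts[a, b, c])])


def write_profile_csv(profile: LayerProfile, path: Union[str, Path]) -> None:
    """Export the layer profile as (k, z_lo, z_hi, occupancy) rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["k", "z_lo", "z_hi", "occupancy"])
        for k in range(profile.spec.nz):
            z_lo, z_hi = profile.spec.layer_z(k)
            w.writerow([k, f"{z_lo:.6g}", f"{z_hi:.6g}", f"{profile.occupancy[k]:.10g}"])
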