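"""Plot-level point clouds: reading, buffer clipping, subplot partitioning.

Coordinates are metres. A plot is an axis-aligned rectangle (default
45 x 45 m); an edge buffer (default 2 m) is stripped to avoid edge
effects, and the buffered interior is divided into four equal quadrant
subplots labelled SW, SE, NW, NE.

All spatial membership tests use half-open intervals ``[lo, hi)`` on x
and y, so clipping and quadrant assignment form exact partitions with
no double counting; a point exactly on a midline belongs to the
higher-coordinate (east / north) side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "PointCloud",
    "PlotGeometry",
    "read_cloud",
    "write_cloud",
    "clip_buffer",
    "split_subplots",
    "normalize_heights",
]

SUBPLOT_LABELS = ("SW", "SE", "NW", "NE")


@dataclass(frozen=True)
class PointCloud:
    """A set of 3D points (metres) with a provenance label.

    ``xyz`` is an (n, 3) float array; it may be empty. All coordinates
    must be finite.
    """

    xyz: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.xyz, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 3)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"xyz must be (n, 3), got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "xyz", arr)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def translated(self, dx: float, dy: float, dz: float = 0.0) -> "PointCloud":
        return replace(self, xyz=self.xyz + np.array([dx, dy, dz]))


@dataclass(frozen=True)
class PlotGeometry:
    """Footprint of one experimental plot.

    ``origin`` is the (x, y) of the lower-left corner; ``side_x`` and
    ``side_y`` the outer edge lengths; ``buffer`` the edge strip removed
    before analysis. The buffered interior is split into 2 x 2 equal
    quadrants.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    side_x: float = 45.0
    side_y: float = 45.0
    buffer: float = 2.0

    def __post_init__(self) -> None:
        if self.buffer < 0:
            raise ValueError("buffer must be non-negative")
        if self.side_x - 2 * self.buffer <= 0 or self.side_y - 2 * self.buffer <= 0:
            raise ValueError("buffer leaves no interior: side - 2*buffer must be > 0")

    @property
    def inner_bounds(self) -> tuple[float, float, float, float]:
        """(x_lo, y_lo, x_hi, y_hi) of the buffered interior."""
        x0, y0 = self.origin
        return (
            x0 + self.buffer,
            y0 + self.buffer,
            x0 + self.side_x - self.buffer,
            y0 + self.side_y - self.buffer,
        )

    @property
    def midlines(self) -> tuple[float, float]:
        x_lo, y_lo, x_hi, y_hi = self.inner_bounds
        return (0.5 * (x_lo + x_hi), 0.5 * (y_lo + y_hi))

    def subplot_bounds(self, label: str) -> tuple[float, float, float, float]:
        """Half-open (x_lo, y_lo, x_hi, y_hi) footprint of one quadrant."""
        if label not in SUBPLOT_LABELS:
            raise ValueError(f"unknown subplot label {label!r}; expected one of {SUBPLOT_LABELS}")
        x_lo, y_lo, x_hi, y_hi = self.inner_bounds
        mx, my = self.midlines
        xs = (x_lo, mx) if label in ("SW", "NW") else (mx, x_hi)
        ys = (y_lo, my) if label in ("SW", "SE") else (my, y_hi)
        return (xs[0], ys[0], xs[1], ys[1])


def read_cloud(path: Union[str, Path], fmt: str = "xyz", source_id: str | None = None) -> PointCloud:
    """Read a point cloud from disk.

    ``fmt='xyz'`` reads ASCII text, one point per line, whitespace- or
    comma-delimited, with at least three numeric columns (extra columns
    are ignored). ``fmt='las'`` reads LAS/LAZ via the optional ``laspy``
    dependency. Point order is preserved.

    Raises
    ------
    ValueError
        On an unknown format, or on a malformed row (the error names the
        offending 1-based line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = source_id if source_id is not None else path.stem
    if fmt == "xyz":
        return _read_xyz(path, sid)
    if fmt == "las":
        return _read_las(path, sid)
    raise ValueError(f"unknown point-cloud format {fmt!r}; expected 'xyz' or 'las'")


def _read_xyz(path: Path, source_id: str) -> PointCloud:
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 numeric columns, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric coordinate: {exc}") from None
    return PointCloud(np.array(rows, dtype=float).reshape(len(rows), 3), source_id=source_id)


def _read_las(path: Path, source_id: str) -> PointCloud:
    try:
        import laspy
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "LAS/LAZ reading requires the optional 'laspy' dependency "
            "(pip install canopyfill[las]); ASCII XYZ is the reference format"
        ) from exc
    las = laspy.read(str(path))  # pragma: no cover - optional dependency
    return PointCloud(np.column_stack([las.x, las.y, las.z]), source_id=source_id)  # pragma: no cover


def write_cloud(cloud: PointCloud, path: Union[str, Path]) -> None:
    """Write a cloud as ASCII XYZ (full float precision, round-trip safe)."""
    np.savetxt(path, cloud.xyz, fmt="%.17g", delimiter=" ")


def clip_buffer(cloud: PointCloud, geom: PlotGeometry) -> PointCloud:
    """Remove points in the plot's edge buffer strip.

    Retains exactly the points whose (x, y) fall in the half-open
    buffered rectangle ``[origin + buffer, origin + side - buffer)``;
    z is untouched. The result may be empty.
    """
    x_lo, y_lo, x_hi, y_hi = geom.inner_bounds
    xyz = cloud.xyz
    keep = (
        (xyz[:, 0] >= x_lo)
        & (xyz[:, 0] < x_hi)
        & (xyz[:, 1] >= y_lo)
        & (xyz[:, 1] < y_hi)
    )
    return replace(cloud, xyz=xyz[keep])


def split_subplots(cloud: PointCloud, geom: PlotGeometry) -> dict[str, PointCloud]:
    """Partition a buffer-clipped cloud into the four quadrant subplots.

    Every retained point lands in exactly one quadrant; points on a
    midline go to the east / north side (half-open convention). Returns
    ``{label: cloud}`` in the fixed order SW, SE, NW, NE. Points outside
    the buffered interior (present if the input was not clipped) are
    dropped.
    """
    out: dict[str, PointCloud] = {}
    xyz = cloud.xyz
    mx, my = geom.midlines
    x_lo, y_lo, x_hi, y_hi = geom.inner_bounds
    east = xyz[:, 0] >= mx
    north = xyz[:, 1] >= my
    inside = (
        (xyz[:, 0] >= x_lo)
        & (xyz[:, 0] < x_hi)
        & (xyz[:, 1] >= y_lo)
        & (xyz[:, 1] < y_hi)
    )
    masks = {
        "SW": ~east & ~north,
        "SE": east & ~north,
        "NW": ~east & north,
        "NE": east & north,
    }
    for label in SUBPLOT_LABELS:
        sel = masks[label] & inside
        sid = f"{cloud.source_id}:{label}" if cloud.source_id else label
        out[label] = PointCloud(xyz[sel], source_id=sid)
    return out


def normalize_heights(cloud: PointCloud, cell: float = 1.0) -> PointCloud:
    """Reference heights to a simple lowest-point ground model.

    The horizontal plane is tiled with square cells of side ``cell``;
    within each cell the minimum z is treated as local ground and
    subtracted, so every output z is >= 0. This is a deliberately plain
    terrain model: adequate for gentle terrain, biased high wherever a
    cell contains no ground return.
    """
    if cloud.is_empty:
        raise ValueError("cannot normalize an empty cloud")
    if cell <= 0:
        raise ValueError("cell must be positive")
    xyz = cloud.xyz
    ci = np.floor(xyz[:, 0] / cell).astype(np.int64)
    cj = np.floor(xyz[:, 1] / cell).astype(np.int64)
    # dense per-cell minima over the occupied cell range
    ci -= ci.min()
    cj -= cj.min()
    ncols = cj.max() + 1
    flat = ci * ncols + cj
    order = np.argsort(flat, kind="stable")
    ground = np.empty(len(xyz))
    sorted_flat = flat[order]
    sorted_z = xyz[order, 2]
    boundaries = np.flatnonzero(np.diff(sorted_flat)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(flat)]])
    mins = np.minimum.reduceat(sorted_z, starts)
    for s, e, m in zip(starts, ends, mins):
        ground[order[s:e]] = m
    out = xyz.copy()
    out[:, 2] -= ground
    return replace(cloud, xyz=out)
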