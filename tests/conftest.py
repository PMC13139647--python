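import numpy as np
import pytest

from canopyfill.voxel import GridSpec, VoxelGrid


def build_gstar() -> VoxelGrid:
    """Hand-built reference grid: 10 x 10 footprint, 10 layers, 0.4 m
    voxels; the bottom five layers fully occupied, the top five layers
    with 5 occupied voxels each (5% occupancy)."""
    counts = np.zeros((10, 10, 10), dtype=np.int64)
    counts[:, :, :5] = 1
    for k in range(5, 10):
        for m in range(5):
            counts[m, (2 * m + k) % 10, k] = 1
    return VoxelGrid(GridSpec((0.0, 0.0, 0.0), 0.4, (10, 10, 10)), counts)


@pytest.fixture
def gstar() -> VoxelGrid:
    return build_gstar()


def brute_force_voxel_counts(xyz: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Independent all-pairs voxel assignment: for every cell, count the
    points inside its half-open box by direct interval tests."""
    nx, ny, nz = spec.shape
    ox, oy, oz = spec.origin
    e = spec.edge
    x_masks = [(xyz[:, 0] >= ox + i * e) & (xyz[:, 0] < ox + (i + 1) * e) for i in range(nx)]
    y_masks = [(xyz[:, 1] >= oy + j * e) & (xyz[:, 1] < oy + (j + 1) * e) for j in range(ny)]
    z_masks = [(xyz[:, 2] >= oz + k * e) & (xyz[:, 2] < oz + (k + 1) * e) for k in range(nz)]
    counts = np.zeros(spec.shape, dtype=np.int64)
    for i in range(nx):
        for j in range(ny):
            mxy = x_masks[i] & y_masks[j]
            if not mxy.any():
                continue
            for k in range(nz):
                counts[i, j, k] = int((mxy & z_masks[k]).sum())
    return counts
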