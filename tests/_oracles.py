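"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: labeling by explicit
flood fill, moments by per-voxel Python loops, medians by per-voxel
neighbourhood sorting.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def connectivity_offsets(connectivity: int):
    """Neighbour offsets for 6/18/26-connectivity in 3D."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                nonzero = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and nonzero > 1:
                    continue
                if connectivity == 18 and nonzero > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """Number of connected components by BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    offs = connectivity_offsets(connectivity)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        q = deque([start])
        seen[start] = True
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offs:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1]
                        and 0 <= nx < mask.shape[2] and mask[nz, ny, nx]
                        and not seen[nz, ny, nx]):
                    seen[nz, ny, nx] = True
                    q.append((nz, ny, nx))
    return count


def brute_force_moments(mask: np.ndarray, pixel_size_xy: float, z_step: float):
    """Volume, centroid and central moment tensors by explicit summation."""
    mask = np.asarray(mask, dtype=bool)
    voxels = list(zip(*np.nonzero(mask)))
    vv = pixel_size_xy * pixel_size_xy * z_step
    volume = vv * len(voxels)
    sx = sy = sz = 0.0
    for z, y, x in voxels:
        sx += x * pixel_size_xy
        sy += y * pixel_size_xy
        sz += z * z_step
    cx, cy, cz = (s / len(voxels) for s in (sx, sy, sz))
    m2 = np.zeros((3, 3))
    m3 = np.zeros((3, 3, 3))
    for z, y, x in voxels:
        d = (x * pixel_size_xy - cx, y * pixel_size_xy - cy, z * z_step - cz)
        for i in range(3):
            for j in range(3):
                m2[i, j] += vv * d[i] * d[j]
                for k in range(3):
                    m3[i, j, k] += vv * d[i] * d[j] * d[k]
    return volume, np.array([cx, cy, cz]), m2, m3


def brute_force_binary_median(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Per-voxel majority over the footprint with reflected boundaries."""
    mask = np.asarray(mask, dtype=bool)
    r = footprint.shape[0] // 2
    padded = np.pad(mask, r, mode="symmetric")  # scipy's "reflect" convention
    out = np.zeros_like(mask)
    offs = [
        (dz - r, dy - r, dx - r)
        for dz in range(footprint.shape[0])
        for dy in range(footprint.shape[1])
        for dx in range(footprint.shape[2])
        if footprint[dz, dy, dx]
    ]
    half = len(offs) / 2.0
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                votes = sum(
                    padded[z + r + dz, y + r + dy, x + r + dx] for dz, dy, dx in offs
                )
                out[z, y, x] = votes > half
    return out
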