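"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately naive pure Python (if-chains, BFS flood
fill, two-pass labelling, per-column loops) and shares no code with the
package's vectorised/scipy-based implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bin_of_hu(h: int) -> int:
    """Per-voxel if-chain for the 12-interval scheme (0 = below range)."""
    if h < 100:
        return 0
    if h <= 200:
        return 1
    if h <= 300:
        return 2
    if h <= 400:
        return 3
    if h <= 500:
        return 4
    if h <= 600:
        return 5
    if h <= 700:
        return 6
    if h <= 800:
        return 7
    if h <= 900:
        return 8
    if h <= 1000:
        return 9
    if h <= 1100:
        return 10
    if h <= 1200:
        return 11
    return 12


def bin_labels_oracle(hu: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros(hu.shape, dtype=np.uint8)
    for idx in np.ndindex(hu.shape):
        if mask[idx]:
            out[idx] = bin_of_hu(int(hu[idx]))
    return out


def interval_counts_oracle(values) -> np.ndarray:
    counts = np.zeros(12, dtype=np.int64)
    for v in values:
        b = bin_of_hu(int(v))
        if b:
            counts[b - 1] += 1
    return counts


def flood_fill_26(mask: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    """Breadth-first 26-connected flood fill from a seed voxel."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    if not mask[seed]:
        raise ValueError("seed outside mask")
    nx, ny, nz = mask.shape
    q = deque([seed])
    out[seed] = True
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    while q:
        x, y, z = q.popleft()
        for dx, dy, dz in offsets:
            i, j, k = x + dx, y + dy, z + dz
            if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz and mask[i, j, k] and not out[i, j, k]:
                out[i, j, k] = True
                q.append((i, j, k))
    return out


def column_max_oracle(hu: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-(x, y) column maximum HU over mask voxels; NaN where no voxel."""
    nx, ny, nz = hu.shape
    out = np.full((nx, ny), np.nan)
    for x in range(nx):
        for y in range(ny):
            best = None
            for z in range(nz):
                if mask[x, y, z]:
                    v = int(hu[x, y, z])
                    if best is None or v > best:
                        best = v
            if best is not None:
                out[x, y] = best
    return out


def label_components_8(hot: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected 2D components by BFS; returns pixel sets sorted by size."""
    hot = np.asarray(hot, dtype=bool)
    nx, ny = hot.shape
    seen = np.zeros_like(hot)
    comps: list[set[tuple[int, int]]] = []
    for x in range(nx):
        for y in range(ny):
            if hot[x, y] and not seen[x, y]:
                comp = set()
                q = deque([(x, y)])
                seen[x, y] = True
                while q:
                    i, j = q.popleft()
                    comp.add((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            if di == dj == 0:
                                continue
                            a, b = i + di, j + dj
                            if 0 <= a < nx and 0 <= b < ny and hot[a, b] and not seen[a, b]:
                                seen[a, b] = True
                                q.append((a, b))
                comps.append(comp)
    return sorted(comps, key=len, reverse=True)
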