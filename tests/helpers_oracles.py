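"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: direct summation
instead of scipy's separable filters, exhaustive subsequence enumeration
instead of the DAG dynamic programme, breadth-first flood fill instead of
scipy's component labelling.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


# ---- direct convolution ----------------------------------------------------

def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Truncated, normalized Gaussian taps (same support rule as scipy)."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def direct_convolve_3d(data: np.ndarray, kernel_1d: np.ndarray) -> np.ndarray:
    """Direct (non-separated) 3D convolution with symmetric edge reflection."""
    r = (len(kernel_1d) - 1) // 2
    k3 = (
        kernel_1d[:, None, None]
        * kernel_1d[None, :, None]
        * kernel_1d[None, None, :]
    )
    padded = np.pad(data, r, mode="symmetric")
    out = np.zeros_like(data, dtype=np.float64)
    nz, ny, nx = data.shape
    for dz in range(2 * r + 1):
        for dy in range(2 * r + 1):
            for dx in range(2 * r + 1):
                out += k3[dz, dy, dx] * padded[dz:dz + nz, dy:dy + ny, dx:dx + nx]
    return out


def direct_gaussian_mean_difference(
    data: np.ndarray, sigma: float, mean_width: int
) -> np.ndarray:
    """Reference band-pass: direct Gaussian minus direct mean filter."""
    mean_kernel = np.full(mean_width, 1.0 / mean_width)
    return direct_convolve_3d(data, gaussian_kernel_1d(sigma)) - direct_convolve_3d(
        data, mean_kernel
    )


# ---- exhaustive longest common subsequence of permutations -----------------

def _is_subseq(candidate, sequence) -> bool:
    it = iter(sequence)
    return all(x in it for x in candidate)


def brute_force_lcs(orderings: list[list[int]]) -> int:
    """Longest common subsequence length over all subsets of the first sample."""
    base = orderings[0]
    for length in range(len(base), 0, -1):
        for subset in combinations(base, length):
            if all(_is_subseq(subset, o) for o in orderings[1:]):
                return length
    return 0


def brute_force_common_subsequences(orderings: list[list[int]], length: int):
    """All common subsequences of exactly ``length`` (sorted)."""
    base = orderings[0]
    found = [
        subset
        for subset in combinations(base, length)
        if all(_is_subseq(subset, o) for o in orderings[1:])
    ]
    return sorted(found)


# ---- flood-fill connected components ---------------------------------------

def flood_fill_components(grid: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a binary 3D grid as voxel-index sets."""
    if connectivity == 6:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    grid = np.asarray(grid, dtype=bool)
    seen = np.zeros_like(grid, dtype=bool)
    components = []
    for start in zip(*np.nonzero(grid)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = {start}
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[a] < grid.shape[a] for a in range(3)) and grid[n] and not seen[n]:
                    seen[n] = True
                    comp.add(n)
                    queue.append(n)
        components.append(frozenset(comp))
    return components
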