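"""Independent brute-force oracles for the texture matrices.

These deliberately use naive per-voxel Python loops (O(V * directions))
and share no code with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def glcm_oracle(arr: np.ndarray, Z: int, d: int, directions, symmetric: bool) -> np.ndarray:
    """Pair-enumeration co-occurrence matrix (normalized)."""
    C = np.zeros((Z, Z), dtype=float)
    for v in np.ndindex(arr.shape):
        if arr[v] < 0:
            continue
        for dd in directions:
            w = tuple(v[i] + d * dd[i] for i in range(3))
            if all(0 <= w[i] < arr.shape[i] for i in range(3)) and arr[w] >= 0:
                C[arr[v], arr[w]] += 1
                if symmetric:
                    C[arr[w], arr[v]] += 1
    return C / C.sum()


def rlm_oracle(arr: np.ndarray, directions) -> dict[tuple[int, int], int]:
    """Scanline run counter: {(level, length): count} over all directions."""
    runs: dict[tuple[int, int], int] = {}
    for dd in directions:
        for v in np.ndindex(arr.shape):
            if arr[v] < 0:
                continue
            p = tuple(v[i] - dd[i] for i in range(3))
            if all(0 <= p[i] < arr.shape[i] for i in range(3)) and arr[p] == arr[v]:
                continue  # continuation, not a run start
            length = 0
            w = v
            while all(0 <= w[i] < arr.shape[i] for i in range(3)) and arr[w] == arr[v]:
                length += 1
                w = tuple(w[i] + dd[i] for i in range(3))
            key = (int(arr[v]), length)
            runs[key] = runs.get(key, 0) + 1
    return runs


def runs_to_matrix(runs: dict[tuple[int, int], int], Z: int) -> np.ndarray:
    lmax = max((length for _, length in runs), default=1)
    R = np.zeros((Z, lmax), dtype=np.int64)
    for (level, length), count in runs.items():
        R[level, length - 1] += count
    return R


def random_masked_volume(rng: np.random.Generator, Z: int = 4, shape=(6, 6, 6), p_mask: float = 0.7):
    arr = rng.integers(0, Z, size=shape).astype(np.int32)
    mask = rng.random(shape) < p_mask
    arr[~mask] = -1
    if not mask.any():  # force one in-mask voxel
        mask[0, 0, 0] = True
        arr[0, 0, 0] = 0
    return arr, mask
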