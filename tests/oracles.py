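"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths of the package: Dice via set
arithmetic on coordinate tuples, boundaries via explicit neighbour
loops, HD95 via all-pairs distance matrices, connected components via
hand-written flood fill, percentile normalization via a sort-based
percentile.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def dice_oracle(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(c) for c in np.argwhere(a)}
    sb = {tuple(c) for c in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def boundary_oracle(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a 6-neighbour outside the mask (edges count)."""
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for idx in np.argwhere(mask):
        i, j, k = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                out[i, j, k] = True
                break
            if not mask[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def hd95_oracle(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs distance matrix between boundary voxel sets, directed 95th
    percentiles, symmetric maximum."""
    spacing = np.asarray(spacing, dtype=np.float64)
    pa = np.argwhere(boundary_oracle(a)) * spacing
    pb = np.argwhere(boundary_oracle(b)) * spacing
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    d_ab = np.percentile(dmat.min(axis=1), 95.0)
    d_ba = np.percentile(dmat.min(axis=0), 95.0)
    return float(max(d_ab, d_ba))


def flood_fill_components(mask: np.ndarray, connectivity: int = 26):
    """List of components (as voxel-index sets) via breadth-first flood fill."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    visited = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in np.argwhere(mask):
        s = tuple(start)
        if visited[s]:
            continue
        comp = set()
        q = deque([s])
        visited[s] = True
        while q:
            cur = q.popleft()
            comp.add(cur)
            for off in offsets:
                nxt = tuple(np.add(cur, off))
                if all(0 <= nxt[d] < mask.shape[d] for d in range(3)) and \
                        mask[nxt] and not visited[nxt]:
                    visited[nxt] = True
                    q.append(nxt)
        comps.append(comp)
    return comps


def percentile_oracle(values: np.ndarray, q: float) -> float:
    """Sort-based linear-interpolation percentile, written independently."""
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def ellipsoid_count_oracle(shape, center, semiaxes) -> int:
    """Direct voxel-by-voxel ellipsoid membership count."""
    count = 0
    a, b, c = semiaxes
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if ((i - center[0]) / a) ** 2 + ((j - center[1]) / b) ** 2 + \
                        ((k - center[2]) / c) ** 2 <= 1.0:
                    count += 1
    return count
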