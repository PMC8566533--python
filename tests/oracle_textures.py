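"""Independent brute-force oracles for the texture matrices.

Deliberately naive: explicit Python loops over voxels, neighbour offsets and
zone flood fills, with no shared code or vectorization tricks from the
implementation under test.
"""

from __future__ import annotations

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
OFFSETS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def _in_bounds(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


def bf_glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric distance-1 GLCM summed over the 13 unique 3D directions."""
    counts = np.zeros((ng, ng), dtype=np.int64)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for off in OFFSETS_13:
                    q = (x + off[0], y + off[1], z + off[2])
                    if not _in_bounds(q, shape):
                        continue
                    b = levels[q]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    return counts


def bf_gldm(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """GLDM: per voxel, count 26-neighbours with |level difference| <= alpha."""
    counts = np.zeros((ng, 27), dtype=np.int64)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                dep = 0
                for off in OFFSETS_26:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(q, shape) and levels[q] != 0 and abs(int(levels[q]) - int(a)) <= alpha:
                        dep += 1
                counts[a - 1, dep] += 1
    return counts


def bf_glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    """GLSZM: 26-connected equal-level zones counted by (level, size)."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: list[tuple[int, int]] = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for off in OFFSETS_26:
                        q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                        if _in_bounds(q, shape) and not seen[q] and levels[q] == g:
                            seen[q] = True
                            stack.append(q)
                zones.append((int(g), size))
    smax = max(s for _, s in zones)
    counts = np.zeros((ng, smax), dtype=np.int64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return counts


def bf_ngtdm(levels: np.ndarray, ng: int) -> np.ndarray:
    """NGTDM: per level, (n_i, p_i, s_i) with s_i the summed absolute
    deviation of each voxel from the mean of its valid 26-neighbours."""
    shape = levels.shape
    table = np.zeros((ng, 3), dtype=np.float64)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                nb = []
                for off in OFFSETS_26:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(q, shape) and levels[q] != 0:
                        nb.append(int(levels[q]))
                if not nb:
                    continue
                table[a - 1, 0] += 1
                table[a - 1, 2] += abs(float(a) - sum(nb) / len(nb))
    nv = table[:, 0].sum()
    if nv > 0:
        table[:, 1] = table[:, 0] / nv
    return table
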