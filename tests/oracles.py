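"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops over voxels, with no
code shared with the package, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

OFFSETS_2D = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def quantize_oracle(values: np.ndarray, ng: int) -> np.ndarray:
    """Sort-and-split equal-probability levels for a flat value array."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    srt = values[order]
    # threshold k = smallest value with ECDF >= k/ng
    thresholds = [srt[int(np.ceil(n * k / ng)) - 1] for k in range(1, ng)]
    levels = np.empty(n, dtype=int)
    for i, v in enumerate(values):
        levels[i] = 1 + sum(1 for t in thresholds if v > t)
    return levels


def glcm_oracle(levels: np.ndarray, ng: int, direction: int) -> np.ndarray:
    """Symmetric normalized co-occurrence by explicit pair enumeration."""
    dy, dx = OFFSETS_2D[direction]
    counts = np.zeros((ng, ng))
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = levels[z, y, x]
                if a == 0:
                    continue
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < ny and 0 <= x2 < nx:
                    b = levels[z, y2, x2]
                    if b > 0:
                        counts[a - 1, b - 1] += 1
                        counts[b - 1, a - 1] += 1
    s = counts.sum()
    return counts / s if s > 0 else counts


def glrlm_oracle(levels: np.ndarray, ng: int, direction: int, lmax: int) -> np.ndarray:
    """Run lengths by walking each scan line voxel by voxel."""
    dy, dx = OFFSETS_2D[direction]
    nz, ny, nx = levels.shape
    M = np.zeros((ng, lmax))
    for z in range(nz):
        # line starts: cells whose predecessor along (dy,dx) is outside
        for y in range(ny):
            for x in range(nx):
                py, px = y - dy, x - dx
                if 0 <= py < ny and 0 <= px < nx:
                    continue  # not a line start
                run_level, run_len = 0, 0
                cy, cx = y, x
                while 0 <= cy < ny and 0 <= cx < nx:
                    v = levels[z, cy, cx]
                    if v == run_level:
                        run_len += 1
                    else:
                        if run_level > 0:
                            M[run_level - 1, run_len - 1] += 1
                        run_level, run_len = v, 1
                    cy, cx = cy + dy, cx + dx
                if run_level > 0:
                    M[run_level - 1, run_len - 1] += 1
    return M


def glszm_oracle(levels: np.ndarray, ng: int) -> dict[tuple[int, int], int]:
    """Zones by recursive flood fill over the 26-neighbourhood."""
    nz, ny, nx = levels.shape
    seen = np.zeros(levels.shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    nbrs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if levels[z, y, x] == 0 or seen[z, y, x]:
                    continue
                lev = levels[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in nbrs:
                        tz, ty, tx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx
                            and not seen[tz, ty, tx]
                            and levels[tz, ty, tx] == lev
                        ):
                            seen[tz, ty, tx] = True
                            stack.append((tz, ty, tx))
                zones[(lev, size)] = zones.get((lev, size), 0) + 1
    return zones


def ngtdm_oracle(levels: np.ndarray, ng: int):
    """Per-level (p, s, n) by explicit neighbourhood averaging."""
    nz, ny, nx = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = levels[z, y, x]
                if v == 0:
                    continue
                nb = []
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            tz, ty, tx = z + dz, y + dy, x + dx
                            if 0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx:
                                if levels[tz, ty, tx] > 0:
                                    nb.append(levels[tz, ty, tx])
                if nb:
                    n[v - 1] += 1
                    s[v - 1] += abs(v - float(np.mean(nb)))
    tot = n.sum()
    p = n / tot if tot > 0 else n
    return p, s, n


def auc_rank_oracle(scores, labels) -> float:
    """AUC = U / (n1 n0) from an explicitly computed rank-sum U."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos) * len(neg))


def random_masked_levels(rng: np.random.Generator, shape=(3, 5, 5), ng: int = 8) -> np.ndarray:
    """Random quantized grid: levels 1..ng inside a random mask, 0 outside."""
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < 0.7
    return np.where(mask, levels, 0).astype(np.int32)
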