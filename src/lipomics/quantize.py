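"""Equal-probability gray-level quantization and texture matrix construction.

Masked intensities are discretised into ``Ng`` levels whose decision
thresholds are empirical quantiles, so every reconstructed level holds
(as nearly as ties allow) the same number of voxels.  From the
quantized volume four texture matrices are built:

* GLCM — gray-level co-occurrence, four in-plane directions (0°, 45°,
  90°, 135°) at offset 1, counts pooled over axial slices, symmetrized
  and normalized;
* GLRLM — gray-level run length along the same four in-plane directions;
* GLSZM — gray-level size zones, 3D 26-connected;
* NGTDM — neighbourhood gray-tone difference, 3D 26-neighbourhood.

Voxels whose offset partner or neighbour lies outside the mask simply
do not contribute (no padding).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from lipomics.preprocessing import ResampledVolume

NG_LADDER = (8, 16, 24, 32, 40, 48, 64)
DIRECTIONS = (0, 45, 90, 135)

# in-plane (dy, dx) offsets for the four classic angles, rows = y down
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclasses.dataclass
class QuantizedVolume:
    """Integer levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray  # 3D int array
    Ng: int
    thresholds: np.ndarray  # Ng-1 ascending reals

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


def equal_probability_quantize(v: ResampledVolume | object, Ng: int) -> QuantizedVolume:
    """Quantize masked intensities into Ng near-equiprobable levels.

    Threshold k (k = 1..Ng-1) is the smallest masked intensity whose
    empirical CDF reaches k/Ng; ties all map to the lower level.  With
    all-distinct intensities the level occupancies differ by at most 1.
    """
    if Ng < 2:
        raise ValueError("Ng must be >= 2")
    mask = np.asarray(v.mask, dtype=bool)
    vals = np.asarray(v.intensities, dtype=np.float64)[mask]
    if vals.size < Ng:
        raise ValueError(f"masked voxel count {vals.size} < Ng {Ng}")
    n_distinct = np.unique(vals).size
    if n_distinct < Ng:
        raise ValueError(
            f"only {n_distinct} distinct masked intensities for Ng={Ng} levels"
        )
    srt = np.sort(vals)
    n = srt.size
    ks = np.arange(1, Ng)
    idx = np.ceil(n * ks / Ng).astype(int) - 1
    thresholds = srt[idx]
    levels = np.zeros(mask.shape, dtype=np.int32)
    # level = 1 + number of thresholds strictly below the value
    levels[mask] = np.searchsorted(thresholds, vals, side="left") + 1
    return QuantizedVolume(levels, Ng, thresholds)


# ----------------------------------------------------------------------
# GLCM


def build_glcm(q: QuantizedVolume, direction: int) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix for one in-plane direction.

    Pairs are accumulated over every axial slice; both voxels of a pair
    must lie inside the mask.  The matrix counts both orderings and is
    normalized to sum 1.
    """
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {sorted(_OFFSETS)}")
    dy, dx = _OFFSETS[direction]
    lev = q.levels
    a, b = _shifted_pairs(lev, dy, dx)
    if a.size == 0:
        raise ValueError("no valid voxel pair for this direction (degenerate geometry)")
    counts = np.zeros((q.Ng, q.Ng), dtype=np.float64)
    np.add.at(counts, (a - 1, b - 1), 1.0)
    counts = counts + counts.T
    return counts / counts.sum()


def _shifted_pairs(lev: np.ndarray, dy: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
    """Level pairs (a, b) at offset (dy, dx) within each slice, both masked."""
    ys = slice(max(0, -dy), lev.shape[1] - max(0, dy))
    xs = slice(max(0, -dx), lev.shape[2] - max(0, dx))
    ys2 = slice(max(0, dy), lev.shape[1] - max(0, -dy))
    xs2 = slice(max(0, dx), lev.shape[2] - max(0, -dx))
    a = lev[:, ys, xs]
    b = lev[:, ys2, xs2]
    ok = (a > 0) & (b > 0)
    return a[ok], b[ok]


# ----------------------------------------------------------------------
# GLRLM


def build_glrlm(q: QuantizedVolume, direction: int) -> np.ndarray:
    """Run-length counts M[i-1, l-1] for one in-plane direction.

    Maximal runs of equal level along the direction, inside the mask,
    per axial slice.  Out-of-mask voxels break runs.
    """
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {sorted(_OFFSETS)}")
    flat = _lines_with_separators(q.levels, direction)
    levels, lengths = _run_lengths(flat)
    keep = levels > 0
    levels, lengths = levels[keep], lengths[keep]
    lmax = max(q.levels.shape[1], q.levels.shape[2])
    M = np.zeros((q.Ng, lmax), dtype=np.float64)
    if levels.size:
        np.add.at(M, (levels - 1, lengths - 1), 1.0)
    return M


def _lines_with_separators(lev: np.ndarray, direction: int) -> np.ndarray:
    """All scan lines of every slice concatenated with 0 separators."""
    nz, ny, nx = lev.shape
    parts: list[np.ndarray] = []
    if direction == 0:  # along x: rows
        padded = np.concatenate([lev, np.zeros((nz, ny, 1), lev.dtype)], axis=2)
        parts.append(padded.reshape(-1))
    elif direction == 90:  # along y: columns
        t = lev.transpose(0, 2, 1)
        padded = np.concatenate([t, np.zeros((nz, nx, 1), lev.dtype)], axis=2)
        parts.append(padded.reshape(-1))
    else:
        # 45°: anti-diagonals (y+x constant); 135°: main diagonals (y-x constant)
        arr = lev[:, ::-1, :] if direction == 45 else lev
        zero = np.zeros(1, dtype=lev.dtype)
        for off in range(-(ny - 1), nx):
            d = np.diagonal(arr, offset=off, axis1=1, axis2=2)  # (nz, L)
            padded = np.concatenate([d, np.zeros((nz, 1), lev.dtype)], axis=1)
            parts.append(padded.reshape(-1))
        parts.append(zero)
    return np.concatenate(parts)


def _run_lengths(flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized run-length encoding of a 1D array."""
    if flat.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [flat.size]])
    return flat[starts].astype(int), (ends - starts).astype(int)


# ----------------------------------------------------------------------
# GLSZM


def build_glszm(q: QuantizedVolume) -> np.ndarray:
    """Size-zone counts M[i-1, z-1]: 3D 26-connected constant-level zones."""
    mask = q.mask
    if not mask.any():
        raise ValueError("empty mask")
    struct = np.ones((3, 3, 3), dtype=int)
    zmax = int(mask.sum())
    M = np.zeros((q.Ng, zmax), dtype=np.float64)
    for i in range(1, q.Ng + 1):
        binary = q.levels == i
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=struct)
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(M, (i - 1, sizes - 1), 1.0)
    # trim trailing all-zero size columns
    nz = np.flatnonzero(M.sum(axis=0))
    return M[:, : nz[-1] + 1] if nz.size else M[:, :1]


# ----------------------------------------------------------------------
# NGTDM


def build_ngtdm(q: QuantizedVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference statistics.

    For every masked voxel with at least one masked 26-neighbour,
    ``|level - mean(masked neighbour levels)|`` is accumulated into the
    voxel's level bin.  Returns ``(p, s, n)`` arrays of length Ng:
    occupancy fraction, summed absolute difference and voxel count per
    level (p sums to 1 over occupied levels).
    """
    mask = q.mask
    if not mask.any():
        raise ValueError("empty mask")
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    maskf = mask.astype(np.float64)
    nb_sum = ndimage.convolve(q.levels * maskf, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(maskf, kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0.5)
    mean_nb = np.zeros_like(nb_sum)
    mean_nb[valid] = nb_sum[valid] / nb_cnt[valid]
    diff = np.abs(q.levels - mean_nb)

    lev_v = q.levels[valid]
    n = np.bincount(lev_v, minlength=q.Ng + 1)[1:].astype(np.float64)
    s = np.zeros(q.Ng)
    np.add.at(s, lev_v - 1, diff[valid])
    nv = n.sum()
    p = n / nv if nv > 0 else n
    return p, s, n


@dataclasses.dataclass
class TextureMatrixSet:
    """All four matrix families for one (volume, Ng) pair."""

    glcm: dict[int, np.ndarray]  # direction -> normalized symmetric matrix
    glrlm: dict[int, np.ndarray]  # direction -> count matrix
    glszm: np.ndarray
    ngtdm: tuple[np.ndarray, np.ndarray, np.ndarray]


def compute_matrices(q: QuantizedVolume) -> TextureMatrixSet:
    return TextureMatrixSet(
        glcm={d: build_glcm(q, d) for d in DIRECTIONS},
        glrlm={d: build_glrlm(q, d) for d in DIRECTIONS},
        glszm=build_glszm(q),
        ngtdm=build_ngtdm(q),
    )
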