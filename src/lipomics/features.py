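"""The fixed 92-feature radiomic catalog and per-case/cohort extraction.

Feature families and counts:

* shape (14) — from the binary mask and spacing only;
* histogram (14) — first-order statistics of raw masked intensities,
  entropy/uniformity on a 256-bin equal-width histogram;
* GLCM (21), GLRLM (13), GLSZM (13), NGTDM (5) — texture statistics on
  equal-probability quantized volumes, computed at every Ng in
  {8, 16, 24, 32, 40, 48, 64} (GLCM/GLRLM additionally at the four
  in-plane directions) and averaged: mean over directions, then mean
  over Ng;
* Gabor (12) — filter bank with 5 scales (half-octave wavelength ladder
  from 3) and 6 orientations; per orientation the mean and SD of the
  masked mean magnitude response across scales.

Matrix feature formulae follow the IBSI reference definitions.
Degenerate-input conventions: correlation-type features with zero
marginal variance return 1; log terms use log2 with 0*log0 = 0; NGTDM
uses eps = 1e-12 with coarseness capped at 1e6.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from skimage import measure
from skimage.filters import gabor_kernel

from lipomics.phantom import VolumeWithMask, read_case
from lipomics.preprocessing import ResampledVolume, resample_isotropic
from lipomics.quantize import (
    DIRECTIONS,
    NG_LADDER,
    QuantizedVolume,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    equal_probability_quantize,
)

_EPS = 1e-12
_COARSENESS_CAP = 1e6

SHAPE_NAMES = [
    "shape_voxel_count",
    "shape_volume_mm3",
    "shape_surface_area_mm2",
    "shape_surface_to_volume_ratio",
    "shape_sphericity",
    "shape_compactness1",
    "shape_compactness2",
    "shape_spherical_disproportion",
    "shape_max_3d_diameter_mm",
    "shape_major_axis_length_mm",
    "shape_minor_axis_length_mm",
    "shape_least_axis_length_mm",
    "shape_elongation",
    "shape_flatness",
]
HIST_NAMES = [
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_median",
    "hist_minimum",
    "hist_maximum",
    "hist_range",
    "hist_p10",
    "hist_p90",
    "hist_iqr",
    "hist_energy",
    "hist_entropy",
    "hist_uniformity",
]
GLCM_NAMES = [
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_idm",
    "glcm_idmn",
    "glcm_id",
    "glcm_idn",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_max_probability",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_variance",
    "glcm_variance",
]
GLRLM_NAMES = [
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_rln",
    "glrlm_run_percentage",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
    "glrlm_glv",
    "glrlm_rlv",
]
GLSZM_NAMES = [
    "glszm_sae",
    "glszm_lae",
    "glszm_gln",
    "glszm_szn",
    "glszm_zone_percentage",
    "glszm_lgze",
    "glszm_hgze",
    "glszm_salge",
    "glszm_sahge",
    "glszm_lalge",
    "glszm_lahge",
    "glszm_glv",
    "glszm_zv",
]
NGTDM_NAMES = [
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
]
GABOR_ORIENTATIONS = tuple(k * np.pi / 6 for k in range(6))
GABOR_WAVELENGTHS = tuple(3.0 * np.sqrt(2.0) ** k for k in range(5))
GABOR_NAMES = [
    f"gabor_{stat}_theta{int(round(np.degrees(t))):03d}"
    for stat in ("mean", "sd")
    for t in GABOR_ORIENTATIONS
]

FEATURE_CATALOG: tuple[str, ...] = tuple(
    SHAPE_NAMES + HIST_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES + GABOR_NAMES
)

_GROUP_SIZES = (14, 14, 21, 13, 13, 5, 12)
assert tuple(
    len(g) for g in (SHAPE_NAMES, HIST_NAMES, GLCM_NAMES, GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES, GABOR_NAMES)
) == _GROUP_SIZES
assert len(FEATURE_CATALOG) == sum(_GROUP_SIZES) == 92
assert len(set(FEATURE_CATALOG)) == 92


# ----------------------------------------------------------------------
# shape


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """14 size/shape descriptors of a single-component binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} 26-connected components, expected 1")
    spacing = np.asarray(spacing, dtype=float)
    voxel_vol = float(np.prod(spacing))
    n_vox = int(mask.sum())
    volume = n_vox * voxel_vol

    # mild smoothing before meshing suppresses the voxel staircase,
    # which otherwise inflates the surface area of round lesions
    padded = ndimage.gaussian_filter(np.pad(mask, 2).astype(np.float64), sigma=0.8)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    compact1 = volume / (np.sqrt(np.pi) * area**1.5)
    compact2 = 36.0 * np.pi * volume**2 / area**3
    sph_dispro = area / (4.0 * np.pi * r_equiv**2)

    coords = np.argwhere(mask) * spacing
    boundary = mask & ~ndimage.binary_erosion(mask)
    bpts = np.argwhere(boundary) * spacing
    if len(bpts) > 5000:
        bpts = bpts[ConvexHull(bpts).vertices]
    max_diam = float(pdist(bpts).max()) if len(bpts) > 1 else 0.0

    cov = np.cov(coords.T, ddof=0) if len(coords) > 1 else np.zeros((3, 3))
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    axes = 4.0 * np.sqrt(eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    vals = [
        float(n_vox),
        volume,
        area,
        area / volume,
        float(sphericity),
        float(compact1),
        float(compact2),
        float(sph_dispro),
        max_diam,
        float(axes[0]),
        float(axes[1]),
        float(axes[2]),
        elongation,
        flatness,
    ]
    return dict(zip(SHAPE_NAMES, vals))


# ----------------------------------------------------------------------
# histogram


def histogram_features(values: np.ndarray, n_bins: int = 256) -> dict[str, float]:
    """14 first-order statistics; entropy/uniformity from a 256-bin histogram."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty intensity sample")
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    else:
        counts = np.array([x.size])
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    vals = [
        float(x.mean()),
        float(x.var()),
        float(_skew(x)) if x.size > 1 and np.ptp(x) > 0 else 0.0,
        float(_kurtosis(x)) if x.size > 1 and np.ptp(x) > 0 else 0.0,
        float(np.median(x)),
        lo,
        hi,
        hi - lo,
        float(np.percentile(x, 10)),
        float(np.percentile(x, 90)),
        float(np.percentile(x, 75) - np.percentile(x, 25)),
        float((x**2).sum()),
        entropy,
        uniformity,
    ]
    return dict(zip(HIST_NAMES, vals))


# ----------------------------------------------------------------------
# matrix features


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """21 co-occurrence statistics of a normalized symmetric GLCM."""
    P = np.asarray(P, dtype=np.float64)
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu = float((I * P).sum())  # symmetric: mu_x == mu_y
    var = float(((I - mu) ** 2 * P).sum())

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    psum = np.zeros(2 * Ng + 1)
    np.add.at(psum, (I + J).ravel(), P.ravel())
    pdiff = np.zeros(Ng)
    np.add.at(pdiff, np.abs(I - J).ravel(), P.ravel())
    ks = np.arange(2 * Ng + 1)
    kd = np.arange(Ng)

    autocorr = float((I * J * P).sum())
    prominence = float(((I + J - 2 * mu) ** 4 * P).sum())
    shade = float(((I + J - 2 * mu) ** 3 * P).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    correlation = float((autocorr - mu * mu) / var) if var > _EPS else 1.0
    diff_entropy = float(-_xlog2(pdiff).sum())
    mu_d = float((kd * pdiff).sum())
    diff_variance = float(((kd - mu_d) ** 2 * pdiff).sum())
    dissimilarity = float((np.abs(I - J) * P).sum())
    energy = float((P**2).sum())
    entropy = float(-_xlog2(P).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())
    idmn = float((P / (1.0 + (I - J) ** 2 / Ng**2)).sum())
    idf = float((P / (1.0 + np.abs(I - J))).sum())
    idn = float((P / (1.0 + np.abs(I - J) / Ng)).sum())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(P * np.where(pxy > 0, np.log2(np.maximum(pxy, _EPS)), 0.0)).sum())
    hxy2 = float(-_xlog2(pxy).sum())
    imc1 = float((entropy - hxy1) / max(hx, hy)) if max(hx, hy) > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    max_prob = float(P.max())
    sum_avg = float((ks * psum).sum())
    sum_entropy = float(-_xlog2(psum).sum())
    sum_variance = float(((ks - sum_avg) ** 2 * psum).sum())

    vals = [
        autocorr, prominence, shade, contrast, correlation, diff_entropy, diff_variance,
        dissimilarity, energy, entropy, idm, idmn, idf, idn, imc1, imc2, max_prob,
        sum_avg, sum_entropy, sum_variance, var,
    ]
    return dict(zip(GLCM_NAMES, vals))


def _rl_stats(M: np.ndarray, n_voxels: int, names: list[str]) -> dict[str, float]:
    """Shared run-length / size-zone statistics (the 13 classic features)."""
    M = np.asarray(M, dtype=np.float64)
    Nr = M.sum()
    if Nr <= 0:
        raise ValueError("empty run/zone matrix")
    Ng, Lmax = M.shape
    i = np.arange(1, Ng + 1)[:, None]
    l = np.arange(1, Lmax + 1)[None, :]
    ri = M.sum(axis=1)
    rl = M.sum(axis=0)
    p = M / Nr
    mu_i = float((i * p).sum())
    mu_l = float((l * p).sum())
    vals = [
        float((M / l**2).sum() / Nr),
        float((M * l**2).sum() / Nr),
        float((ri**2).sum() / Nr),
        float((rl**2).sum() / Nr),
        float(Nr / n_voxels),
        float((M / i**2).sum() / Nr),
        float((M * i**2).sum() / Nr),
        float((M / (i**2 * l**2)).sum() / Nr),
        float((M * i**2 / l**2).sum() / Nr),
        float((M * l**2 / i**2).sum() / Nr),
        float((M * i**2 * l**2).sum() / Nr),
        float(((i - mu_i) ** 2 * p).sum()),
        float(((l - mu_l) ** 2 * p).sum()),
    ]
    return dict(zip(names, vals))


def glrlm_features(M: np.ndarray, n_voxels: int) -> dict[str, float]:
    """13 run-length statistics (SRE, LRE, GLN, RLN, RP, ...)."""
    return _rl_stats(M, n_voxels, GLRLM_NAMES)


def glszm_features(M: np.ndarray, n_voxels: int) -> dict[str, float]:
    """13 size-zone statistics, the zone analogues of the run features."""
    return _rl_stats(M, n_voxels, GLSZM_NAMES)


def ngtdm_features(p: np.ndarray, s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    p = np.asarray(p, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    Nv = n.sum()
    levels = np.arange(1, len(p) + 1, dtype=np.float64)
    occ = p > 0
    iv, pv, sv = levels[occ], p[occ], s[occ]
    ngp = int(occ.sum())

    ps = float((pv * sv).sum())
    coarseness = min(1.0 / max(ps, _EPS), _COARSENESS_CAP)

    if ngp < 2:
        contrast = 0.0
    else:
        di = iv[:, None] - iv[None, :]
        contrast = float(
            (pv[:, None] * pv[None, :] * di**2).sum() / (ngp * (ngp - 1)) * (sv.sum() / Nv)
        )

    ipi = iv * pv
    denom_b = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = ps / denom_b if denom_b > _EPS else 0.0

    if ngp < 2:
        complexity = 0.0
        strength = 0.0
    else:
        di = np.abs(iv[:, None] - iv[None, :])
        num_c = di * (pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :]) / (
            pv[:, None] + pv[None, :]
        )
        complexity = float(num_c.sum() / Nv)
        s_tot = float(sv.sum())
        strength = (
            float(((pv[:, None] + pv[None, :]) * (iv[:, None] - iv[None, :]) ** 2).sum() / s_tot)
            if s_tot > _EPS
            else 0.0
        )

    return dict(
        zip(NGTDM_NAMES, [coarseness, contrast, busyness, complexity, strength])
    )


# ----------------------------------------------------------------------
# Gabor


def _gabor_bank() -> list[tuple[int, int, np.ndarray]]:
    """Zero-mean complex kernels indexed by (scale, orientation)."""
    bank = []
    for si, lam in enumerate(GABOR_WAVELENGTHS):
        for oi, theta in enumerate(GABOR_ORIENTATIONS):
            k = gabor_kernel(frequency=1.0 / lam, theta=theta)
            # DC-free in both quadrature channels: constant image
            # offsets then produce exactly zero response
            k = k - k.mean()
            bank.append((si, oi, k))
    return bank


def gabor_features(v: ResampledVolume | VolumeWithMask) -> dict[str, float]:
    """12 spatial-frequency features from a 5-scale x 6-orientation bank.

    Per filter: mean magnitude response over masked pixels pooled over
    axial slices.  Per orientation: mean and SD of that response across
    the 5 scales.
    """
    mask = np.asarray(v.mask, dtype=bool)
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    if zs.size == 0:
        raise ValueError("empty mask")
    resp = np.zeros((len(GABOR_WAVELENGTHS), len(GABOR_ORIENTATIONS)))
    wsum = 0.0
    bank = _gabor_bank()
    for z in zs:
        sl = np.asarray(v.intensities[z], dtype=np.float64)
        m = mask[z]
        w = float(m.sum())
        for si, oi, k in bank:
            # symmetric padding: no spurious boundary response (a
            # constant image then yields exactly zero magnitude)
            ph, pw = k.shape[0] // 2, k.shape[1] // 2
            slp = np.pad(sl, ((ph, ph), (pw, pw)), mode="symmetric")
            full = fftconvolve(slp, k, mode="same")
            mag = np.abs(full[ph : ph + sl.shape[0], pw : pw + sl.shape[1]])
            resp[si, oi] += mag[m].sum()
        wsum += w
    resp /= wsum
    means = resp.mean(axis=0)
    sds = resp.std(axis=0)
    return dict(zip(GABOR_NAMES, np.concatenate([means, sds])))


# ----------------------------------------------------------------------
# per-case extraction


@dataclasses.dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the extraction stage, frozen per run and recorded in outputs."""

    target_spacing: float = 1.0
    interp: str = "nearest"
    ng_ladder: tuple[int, ...] = NG_LADDER
    directions: tuple[int, ...] = DIRECTIONS

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def extract_case(v: VolumeWithMask, config: ExtractionConfig | None = None) -> dict[str, float]:
    """Compute the full 92-feature vector for one case.

    Shape and histogram features come from the raw resampled data (no
    intensity normalization).  Each matrix feature is computed at every
    Ng of the ladder (GLCM/GLRLM per direction, averaged over the four
    directions) and then averaged over Ng.
    """
    cfg = config or ExtractionConfig()
    rv = resample_isotropic(v, cfg.target_spacing, interp=cfg.interp)
    out: dict[str, float] = {}
    out.update(shape_features(rv.mask, rv.spacing))
    masked = rv.intensities[rv.mask]
    out.update(histogram_features(masked))

    n_vox = int(rv.mask.sum())
    acc = {name: [] for name in GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES}
    for ng in cfg.ng_ladder:
        q = equal_probability_quantize(rv, ng)
        per_dir_glcm = [glcm_features(build_glcm(q, d)) for d in cfg.directions]
        per_dir_glrlm = [glrlm_features(build_glrlm(q, d), n_vox) for d in cfg.directions]
        for name in GLCM_NAMES:
            acc[name].append(np.mean([f[name] for f in per_dir_glcm]))
        for name in GLRLM_NAMES:
            acc[name].append(np.mean([f[name] for f in per_dir_glrlm]))
        for name, val in glszm_features(build_glszm(q), n_vox).items():
            acc[name].append(val)
        for name, val in ngtdm_features(*build_ngtdm(q)).items():
            acc[name].append(val)
    out.update({name: float(np.mean(vs)) for name, vs in acc.items()})

    out.update(gabor_features(rv))
    assert list(out) == list(FEATURE_CATALOG)
    return out


def extract_cohort(
    manifest: pd.DataFrame | str | Path,
    cohort_dir: str | Path | None = None,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """FeatureTable for a cohort manifest: case_id, batch, label + 92 features.

    ``manifest`` is the DataFrame (or CSV path) written by
    :func:`lipomics.phantom.generate_cohort`.  Unreadable cases raise.
    """
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        cohort_dir = cohort_dir or path.parent
        manifest = pd.read_csv(path)
    cohort_dir = Path(cohort_dir) if cohort_dir is not None else Path(".")
    rows = []
    for _, r in manifest.iterrows():
        v = read_case(cohort_dir / r["image"], cohort_dir / r["mask"])
        feats = extract_case(v, config)
        rows.append({"case_id": r["case_id"], "batch": r["batch"], "label": r["label"], **feats})
    return pd.DataFrame(rows, columns=["case_id", "batch", "label", *FEATURE_CATALOG])


def extract_cohort_in_memory(
    spec, config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """FeatureTable straight from a PhantomSpec, without touching disk."""
    from lipomics.phantom import generate_case

    rows = []
    for i in range(spec.n_cases):
        v, batch, label = generate_case(spec, i)
        feats = extract_case(v, config)
        rows.append({"case_id": f"case_{i:04d}", "batch": batch, "label": label, **feats})
    return pd.DataFrame(rows, columns=["case_id", "batch", "label", *FEATURE_CATALOG])
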