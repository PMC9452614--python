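"""Synthetic multi-site phantom cohort with known ground truth.

The generator emulates the situation the pipeline is built for: two
lesion classes that differ in *internal texture heterogeneity* (benign
lesions are smooth; malignant lesions contain nodular hyperintense
inclusions and septum-like hypointense planes), imaged across several
"batches" whose acquisition differs by a multiplicative gain, an
additive offset and a Gaussian blur.  Batch effects are injected at the
image level so that downstream feature harmonization is exercised
against an acquisition-style confounder, not a synthetic feature-level
shift.

Volumes are indexed ``(z, y, x)``; ``spacing`` is millimetres per voxel
in the same order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom cohort; a spec plus a seed is the cohort.

    Parameters
    ----------
    n_cases:
        Number of cases in the cohort.
    class_balance:
        Fraction of malignant cases, in (0, 1).
    n_batches:
        Number of acquisition batches (sites / protocols).
    class_texture_gap:
        Amplitude multiplier for the malignant-only internal texture
        (nodules and septa).  0 makes the class label uninformative.
    batch_gain, batch_offset, batch_blur_sigma:
        Per-batch multiplicative intensity factor, additive shift and
        Gaussian blur width (voxels), each of length ``n_batches``.
    confounding:
        Class-batch correlation in [0, 1].  0 assigns each class evenly
        across batches (independence by construction); 1 sends classes
        to opposite batches as far as counts allow.
    grid_shape, voxel_spacing:
        Volume geometry; spacing in mm (z, y, x).
    lesion_semiaxis_range:
        Range of ellipsoid semi-axes in mm.
    """

    n_cases: int = 85
    class_balance: float = 45 / 85
    n_batches: int = 2
    class_texture_gap: float = 1.0
    batch_gain: tuple[float, ...] = (1.0, 1.5)
    batch_offset: tuple[float, ...] = (0.0, 30.0)
    batch_blur_sigma: tuple[float, ...] = (0.0, 1.5)
    confounding: float = 0.0
    seed: int = 0
    grid_shape: tuple[int, int, int] = (36, 72, 72)
    voxel_spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    lesion_semiaxis_range: tuple[float, float] = (8.0, 20.0)

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if not 0.0 <= self.confounding <= 1.0:
            raise ValueError("confounding must be in [0, 1]")
        if self.class_texture_gap < 0:
            raise ValueError("class_texture_gap must be non-negative")
        for name in ("batch_gain", "batch_offset", "batch_blur_sigma"):
            if len(getattr(self, name)) != self.n_batches:
                raise ValueError(f"{name} must have one entry per batch")
        if any(s <= 0 for s in self.grid_shape) or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("grid_shape and voxel_spacing must be positive")

    # ------------------------------------------------------------------
    def assignments(self) -> pd.DataFrame:
        """Deterministic case -> (label, batch) assignment.

        Labels are stratified exactly by ``class_balance``; with
        ``confounding = 0`` each class is split evenly across batches so
        class and batch are independent by construction.
        """
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xA551]))
        n_mal = int(round(self.n_cases * self.class_balance))
        labels = np.array([1] * n_mal + [0] * (self.n_cases - n_mal))
        rng.shuffle(labels)

        batches = np.zeros(self.n_cases, dtype=int)
        for lab in (0, 1):
            idx = np.flatnonzero(labels == lab)
            rng.shuffle(idx)
            # Batch shares: confounding skews the malignant class toward
            # high batch ids (by convention the heavier-degradation
            # protocols), the benign class toward low batch ids — the
            # adversarial site-quality arrangement.
            w = np.ones(self.n_batches)
            if self.n_batches > 1:
                ramp = np.linspace(-1.0, 1.0, self.n_batches)
                sgn = 1.0 if lab == 1 else -1.0
                w = 1.0 + sgn * self.confounding * ramp
                w = np.clip(w, 0.0, None)
                if w.sum() == 0:
                    w = np.ones(self.n_batches)
            counts = _largest_remainder(w / w.sum() * len(idx))
            start = 0
            for b, c in enumerate(counts):
                batches[idx[start : start + c]] = b
                start += c
        return pd.DataFrame(
            {
                "case_id": [f"case_{i:04d}" for i in range(self.n_cases)],
                "batch": batches,
                "label": labels,
            }
        )


def _largest_remainder(x: np.ndarray) -> np.ndarray:
    """Round non-negative reals to integers preserving the total."""
    base = np.floor(x).astype(int)
    rem = int(round(x.sum())) - base.sum()
    order = np.argsort(-(x - base))
    base[order[:rem]] += 1
    return base


@dataclasses.dataclass
class VolumeWithMask:
    """A 3D intensity volume, its voxel spacing (mm) and a binary lesion mask."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensities and mask shapes differ")
        if self.intensities.ndim != 3:
            raise ValueError("expected a 3D volume")


def study_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The default two-batch cohort preset (85 cases, 45 malignant)."""
    return dataclasses.replace(PhantomSpec(seed=seed), **overrides)


def small_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A scaled-down cohort for quick experiments: smaller grids and lesions."""
    base = PhantomSpec(
        n_cases=40,
        class_balance=0.5,
        seed=seed,
        grid_shape=(24, 48, 48),
        voxel_spacing=(2.0, 1.0, 1.0),
        lesion_semiaxis_range=(6.0, 11.0),
    )
    return dataclasses.replace(base, **overrides)


# ----------------------------------------------------------------------
# single-case generation


def generate_case(spec: PhantomSpec, case_index: int) -> tuple[VolumeWithMask, int, int]:
    """Generate one phantom case.

    Returns ``(volume, batch, label)``.  Deterministic given
    ``(spec.seed, case_index)``: the same pair always yields bit-identical
    arrays.  Benign lesions are a smooth ellipsoid with low-amplitude
    correlated noise; malignant lesions add hyperintense Gaussian nodules
    and hypointense septum-like planes whose amplitude scales with
    ``spec.class_texture_gap``.  The case's batch gain/offset/blur is then
    applied to the whole volume.
    """
    if not 0 <= case_index < spec.n_cases:
        raise IndexError(f"case_index {case_index} out of range [0, {spec.n_cases})")
    table = spec.assignments()
    batch = int(table.batch.iloc[case_index])
    label = int(table.label.iloc[case_index])

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(case_index)]))
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)

    lo, hi = spec.lesion_semiaxis_range
    semiaxes_mm = rng.uniform(lo, hi, size=3)  # (z, y, x) before rotation
    extent_mm = shape * spacing
    for ax, name in enumerate("zyx"):
        if 2 * semiaxes_mm.max() + 4 * spacing[ax] > extent_mm[ax]:
            raise ValueError(
                f"lesion (diameter {2 * semiaxes_mm.max():.1f} mm) does not fit "
                f"grid axis {name} ({extent_mm[ax]:.1f} mm)"
            )

    # physical coordinates of every voxel centre, lesion at volume centre
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    centre = extent_mm / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    pts = np.stack([zz - centre[0], yy - centre[1], xx - centre[2]], axis=-1)

    # random rotation (QR of a Gaussian matrix)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    local = pts @ q
    mask = ((local / semiaxes_mm) ** 2).sum(axis=-1) <= 1.0
    mask = _largest_component(mask)
    if mask.sum() < 27:
        raise ValueError("generated lesion has fewer than 27 voxels")

    # background tissue + smooth lesion signal with fine-grained
    # correlated noise (correlation length ~1 mm, finer than the
    # malignant nodules, so acquisition blur suppresses it faster than
    # it suppresses the class-specific texture)
    vol = 100.0 + rng.normal(0.0, 4.0, size=shape)
    lesion = 200.0 + ndimage.gaussian_filter(rng.normal(0.0, 60.0, size=shape), sigma=1.0 / spacing)
    vol = np.where(mask, lesion, vol)

    if label == 1 and spec.class_texture_gap > 0:
        vol += _malignant_texture(rng, shape, spacing, mask, local, semiaxes_mm, spec.class_texture_gap)

    # batch perturbation at image level; gain/offset carry per-case
    # protocol jitter (sites within a technique do not share one exact
    # protocol), blur is the technique's nominal value
    gain = spec.batch_gain[batch] * float(np.exp(rng.normal(0.0, 0.1)))
    offset = spec.batch_offset[batch] + float(rng.normal(0.0, 12.0))
    blur = spec.batch_blur_sigma[batch]
    if blur > 0:
        vol = ndimage.gaussian_filter(vol, sigma=blur)
    vol = vol * gain + offset

    return VolumeWithMask(vol, tuple(spacing), mask), batch, label


def _malignant_texture(rng, shape, spacing, mask, local, semiaxes_mm, gap):
    """Nodular inclusions + septum-like planes, confined to the mask."""
    tex = np.zeros(shape)
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)

    masked_idx = np.argwhere(mask)
    n_blobs = int(rng.integers(3, 9))
    for _ in range(n_blobs):
        c_vox = masked_idx[rng.integers(len(masked_idx))]
        c_mm = c_vox * spacing
        sig = rng.uniform(1.5, 3.0)
        d2 = ((pts - c_mm) ** 2).sum(axis=-1)
        tex += 35.0 * gap * np.exp(-d2 / (2 * sig**2))

    n_planes = int(rng.integers(1, 4))
    for _ in range(n_planes):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        off = rng.uniform(-0.4, 0.4) * semiaxes_mm.mean()
        dist = np.abs(local @ normal - off)
        thick = rng.uniform(1.5, 2.5)
        tex -= 30.0 * gap * np.exp(-(dist**2) / (2 * thick**2))

    return np.where(mask, tex, 0.0)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


# ----------------------------------------------------------------------
# cohort I/O


def write_nifti(path: Path, array: np.ndarray, spacing: tuple[float, float, float]) -> None:
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    # store as (x, y, z) on disk, the conventional NIfTI order
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32).transpose(2, 1, 0), affine)
    nib.save(img, str(path))


def read_case(image_path: Path, mask_path: Path) -> VolumeWithMask:
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing_xyz = img.header.get_zooms()[:3]
    vol = np.asanyarray(img.dataobj).astype(np.float64).transpose(2, 1, 0)
    mask = np.asanyarray(msk.dataobj).transpose(2, 1, 0) > 0.5
    spacing = (float(spacing_xyz[2]), float(spacing_xyz[1]), float(spacing_xyz[0]))
    return VolumeWithMask(vol, spacing, mask)


def generate_cohort(spec: PhantomSpec, out_dir: str | Path, overwrite: bool = False) -> pd.DataFrame:
    """Write the full cohort to ``out_dir`` and return the manifest.

    One image and one mask NIfTI per case plus ``manifest.csv`` with
    columns ``case_id,batch,label,image,mask``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    rows = []
    for i in range(spec.n_cases):
        vol, batch, label = generate_case(spec, i)
        cid = f"case_{i:04d}"
        img_p = out_dir / f"{cid}_image.nii.gz"
        msk_p = out_dir / f"{cid}_mask.nii.gz"
        if (img_p.exists() or msk_p.exists()) and not overwrite:
            raise FileExistsError(f"refusing to overwrite {img_p}")
        write_nifti(img_p, vol.intensities, vol.spacing)
        write_nifti(msk_p, vol.mask.astype(np.uint8), vol.spacing)
        rows.append(
            {"case_id": cid, "batch": batch, "label": label, "image": img_p.name, "mask": msk_p.name}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest
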