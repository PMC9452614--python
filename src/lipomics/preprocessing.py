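"""Resampling, cropping and intensity normalization shared by both arms.

The radiomics arm consumes *raw* resampled intensities — no intensity
normalization or filtering is applied before feature extraction.  The
CNN arm uses 2D lesion crops resized to a fixed matrix and z-scored per
slice.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize

from lipomics.phantom import VolumeWithMask


@dataclasses.dataclass
class ResampledVolume:
    intensities: np.ndarray
    spacing: tuple[float, float, float]  # isotropic
    mask: np.ndarray


def resample_isotropic(
    v: VolumeWithMask, target_spacing: float = 1.0, interp: str = "nearest"
) -> ResampledVolume:
    """Resample image and mask onto a common isotropic grid.

    The mask is always resampled by nearest-neighbour; the image by
    nearest-neighbour as well by default (``interp='linear'`` switches
    to trilinear).  Already-isotropic input at the target spacing is
    returned unchanged.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if interp not in ("nearest", "linear"):
        raise ValueError("interp must be 'nearest' or 'linear'")
    spacing = np.asarray(v.spacing, dtype=float)
    if spacing.max() / spacing.min() > 20:
        warnings.warn("anisotropy ratio exceeds 20; resampling may be unreliable", stacklevel=2)
    if np.allclose(spacing, target_spacing, atol=1e-12):
        return ResampledVolume(v.intensities.copy(), (target_spacing,) * 3, v.mask.copy())

    zoom = spacing / target_spacing
    order = 0 if interp == "nearest" else 1
    img = ndimage.zoom(v.intensities, zoom, order=order, mode="nearest", grid_mode=True)
    mask = ndimage.zoom(v.mask.astype(np.uint8), zoom, order=0, mode="nearest", grid_mode=True)
    return ResampledVolume(img, (target_spacing,) * 3, mask.astype(bool))


def crop_and_resize_slices(
    v: VolumeWithMask | ResampledVolume,
    out_size: int = 224,
    margin: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract one 2D crop per axial slice intersecting the mask.

    Each slice is cropped to that slice's mask bounding box expanded by
    ``margin`` per side, then resized to ``out_size`` square.  Returns
    ``(images, slice_indices)`` with images of shape ``(n, out_size,
    out_size)``.
    """
    mask = np.asarray(v.mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no slices to crop")
    imgs, idxs = [], []
    for z in range(mask.shape[0]):
        sl = mask[z]
        if not sl.any():
            continue
        ys, xs = np.nonzero(sl)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        my = max(1, int(round((y1 - y0) * margin)))
        mx = max(1, int(round((x1 - x0) * margin)))
        y0, y1 = max(0, y0 - my), min(sl.shape[0], y1 + my)
        x0, x1 = max(0, x0 - mx), min(sl.shape[1], x1 + mx)
        crop = v.intensities[z, y0:y1, x0:x1]
        out = sk_resize(crop, (out_size, out_size), order=1, mode="reflect", anti_aliasing=True)
        imgs.append(out)
        idxs.append(z)
    return np.stack(imgs), np.asarray(idxs)


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """I_new = (I - mu) / sigma with the population standard deviation."""
    image = np.asarray(image, dtype=np.float64)
    sigma = image.std()
    if sigma == 0:
        raise ValueError("constant image: z-score undefined (sigma = 0)")
    return (image - image.mean()) / sigma
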