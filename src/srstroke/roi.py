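"""Peri-infarct region-of-interest construction.

The analysis region is the DWI lesion core plus a surrounding band of
tissue at risk, obtained by morphological dilation of the lesion mask:
20 pixels in-plane for the SWI convention, or a metric distance
(default 2.5 mm, the middle of the 2-3 mm band convention) for CTP.
Dilation is slice-wise 2-D by default because the modalities are matched
interface by interface; a 3-D variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["ROIMask", "segment_dwi_stub", "dilate_pixels", "dilate_mm", "resample_mask"]


@dataclass(frozen=True)
class ROIMask:
    """A 3-D boolean mask with provenance and voxel spacing (mm)."""

    mask: np.ndarray
    voxel_spacing_mm: tuple = (1.0, 1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")
        object.__setattr__(self, "mask", mask)

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


def segment_dwi_stub(dwi_like: np.ndarray, threshold: float,
                     voxel_spacing_mm=(1.0, 1.0, 1.0)) -> ROIMask:
    """Threshold stand-in for a DWI lesion segmenter: mask = voxels >= threshold.

    Synthetic truth masks are the primary lesion source; this stub exists so
    intensity volumes can also be thresholded. An empty result is allowed and
    flagged in provenance.
    """
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    mask = np.asarray(dwi_like, dtype=float) >= threshold
    return ROIMask(mask=mask, voxel_spacing_mm=tuple(voxel_spacing_mm),
                   provenance={"source": "threshold_stub", "threshold": float(threshold),
                               "empty": not bool(mask.any())})


def _dilate_by_distance(mask: np.ndarray, radius: float, sampling) -> np.ndarray:
    """Grow ``mask`` to all voxels within Euclidean ``radius`` (given
    per-axis ``sampling``) of the foreground, via a distance transform."""
    if not mask.any() or radius <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return dist <= radius + 1e-9


def dilate_pixels(roi: ROIMask, n_pixels: int, mode: str = "2d") -> ROIMask:
    """Dilate by Euclidean distance <= ``n_pixels`` in voxel units.

    ``mode='2d'`` (default) dilates each axial slice independently with an
    in-plane disc; ``mode='3d'`` uses a ball. The lesion is always included.
    """
    if n_pixels < 0:
        raise ValueError("n_pixels must be >= 0")
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    mask = roi.mask
    if n_pixels == 0:
        out = mask.copy()
    elif mode == "2d":
        out = np.empty_like(mask)
        for z in range(mask.shape[2]):
            out[:, :, z] = _dilate_by_distance(mask[:, :, z], n_pixels, (1.0, 1.0))
    else:
        out = _dilate_by_distance(mask, n_pixels, (1.0, 1.0, 1.0))
    prov = dict(roi.provenance)
    prov["dilated_pixels"] = prov.get("dilated_pixels", 0) + int(n_pixels)
    prov["dilation_mode"] = mode
    return ROIMask(mask=out, voxel_spacing_mm=roi.voxel_spacing_mm, provenance=prov)


def dilate_mm(roi: ROIMask, distance_mm: float = 2.5, mode: str = "3d") -> ROIMask:
    """Dilate by a metric distance, converted per-axis by the voxel spacing.

    With anisotropic spacing the growth is anisotropic in voxel units (e.g.
    0.5 mm in-plane / 5 mm slices and a 2 mm radius grow 4 voxels in-plane
    and none through-plane).
    """
    if distance_mm < 0:
        raise ValueError("distance_mm must be >= 0")
    spacing = roi.voxel_spacing_mm
    if spacing is None or any(s <= 0 for s in spacing):
        raise ValueError("positive voxel spacing required for metric dilation")
    mask = roi.mask
    if distance_mm == 0:
        out = mask.copy()
    elif mode == "2d":
        out = np.empty_like(mask)
        for z in range(mask.shape[2]):
            out[:, :, z] = _dilate_by_distance(mask[:, :, z], distance_mm, spacing[:2])
    else:
        out = _dilate_by_distance(mask, distance_mm, spacing)
    prov = dict(roi.provenance)
    prov["dilated_mm"] = prov.get("dilated_mm", 0.0) + float(distance_mm)
    prov["dilation_mode"] = mode
    return ROIMask(mask=out, voxel_spacing_mm=spacing, provenance=prov)


def resample_mask(roi: ROIMask, target_shape, target_spacing=None) -> ROIMask:
    """Nearest-neighbor resampling onto another grid (geometry adapter).

    Maps each target voxel center into the source grid assuming aligned
    fields of view; modalities are generated pre-aligned, so no registration
    is involved.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s < 1 for s in target_shape):
        raise ValueError("target_shape must be 3 positive ints")
    src_shape = roi.mask.shape
    if target_shape == src_shape:
        out = roi.mask.copy()
    else:
        coords = np.meshgrid(
            *[(np.arange(t) + 0.5) * s / t - 0.5 for t, s in zip(target_shape, src_shape)],
            indexing="ij",
        )
        coords = [np.clip(np.round(c).astype(int), 0, s - 1) for c, s in zip(coords, src_shape)]
        out = roi.mask[tuple(coords)]
    spacing = tuple(target_spacing) if target_spacing is not None else roi.voxel_spacing_mm
    prov = dict(roi.provenance)
    prov["resampled_to"] = target_shape
    return ROIMask(mask=out, voxel_spacing_mm=spacing, provenance=prov)


def save_mask(roi: ROIMask, path: str) -> None:
    import nibabel as nib

    affine = np.diag(list(roi.voxel_spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), affine), path)


def load_mask(path: str) -> ROIMask:
    import nibabel as nib

    img = nib.load(path)
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return ROIMask(mask=np.asarray(img.dataobj) > 0.5, voxel_spacing_mm=spacing,
                   provenance={"source": path})
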