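"""Pseudo-planar projection, mask projection, dilation, and 2D resampling.

A pseudo-planar image is the sum of a SPECT-like 3D activity volume along the
anterior-posterior axis; with parallel-hole collimation there is no
magnification, so the projection is an axis-aligned sum with a one-to-one pixel
mapping and exact count conservation. Masks project by union along each ray.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import ActivityVolume, LabelMask, PlanarImage


def project_volume(
    vol: ActivityVolume,
    *,
    view: str = "pseudo",
    patient_id: str = "",
    acquisition_id: str = "",
) -> PlanarImage:
    """Sum the volume along its anterior-posterior axis.

    The output is oriented (row, col) = (cranio-caudal, left-right); total
    counts are conserved exactly.
    """
    if vol.ap_axis is None:
        raise ValueError("volume has no declared anterior-posterior axis")
    if vol.ap_axis != 2:
        raise ValueError("convention requires the AP axis to be the third axis")
    pixels = vol.voxels.sum(axis=2).T  # (LR, CC) -> (CC, LR)
    spacing = (vol.spacing_mm[1], vol.spacing_mm[0])
    return PlanarImage(
        pixels, spacing_mm=spacing, view=view,
        patient_id=patient_id, acquisition_id=acquisition_id,
    )


def project_mask(mask3d: LabelMask) -> LabelMask:
    """Union projection: a pixel is foreground iff any voxel along its AP ray is."""
    if mask3d.data.ndim != 3:
        raise ValueError("project_mask expects a 3D mask")
    pixels = mask3d.data.any(axis=2).T
    spacing = (mask3d.spacing_mm[1], mask3d.spacing_mm[0])
    return LabelMask(pixels, structure=mask3d.structure, spacing_mm=spacing)


def _ball_footprint(radii_vox) -> np.ndarray:
    """Ellipsoidal structuring element with per-axis voxel radii >= 1."""
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii_vox)]
    rho2 = sum((g / r) ** 2 for g, r in zip(grids, radii_vox))
    return rho2 <= 1.0


def dilate_mask(mask: LabelMask, radius_mm: float) -> LabelMask:
    """Morphological dilation with a ball/disk of physical radius ``radius_mm``.

    The radius converts to voxels per axis via the spacing, rounded to the
    nearest integer but at least 1 voxel whenever the radius is positive.
    Radius 0 is the identity.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if radius_mm == 0:
        return LabelMask(mask.data.copy(), mask.structure, mask.spacing_mm)
    radii = [max(1, round(radius_mm / s)) for s in mask.spacing_mm]
    out = ndimage.binary_dilation(mask.data, structure=_ball_footprint(radii))
    return LabelMask(out, structure=mask.structure, spacing_mm=mask.spacing_mm)


def _resample_grid(pixels, spacing, target_spacing, order):
    out_shape = tuple(
        max(1, round(n * s / t)) for n, s, t in zip(pixels.shape, spacing, target_spacing)
    )
    if out_shape == pixels.shape and tuple(spacing) == tuple(target_spacing):
        return pixels.copy()
    coords = np.meshgrid(
        *[
            (np.arange(m) + 0.5) * t / s - 0.5
            for m, s, t in zip(out_shape, spacing, target_spacing)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        pixels, np.stack(coords), order=order, mode="nearest"
    )


def resample_2d(img, target_spacing_mm, interpolation: str = "linear"):
    """Resample a planar image (linear) or 2D mask (nearest) to a new spacing.

    The output grid spans the same physical extent; output size per axis is
    ``round(n * spacing / target_spacing)``.
    """
    ts = (float(target_spacing_mm[0]), float(target_spacing_mm[1]))
    if min(ts) <= 0:
        raise ValueError("target spacing must be strictly positive")
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    if isinstance(img, LabelMask):
        out = _resample_grid(img.data.astype(np.float64), img.spacing_mm, ts, order=0)
        return LabelMask(out > 0.5, structure=img.structure, spacing_mm=ts)
    order = 1 if interpolation == "linear" else 0
    out = _resample_grid(img.pixels, img.spacing_mm, ts, order=order)
    return PlanarImage(
        np.clip(out, 0, None), spacing_mm=ts, view=img.view,
        patient_id=img.patient_id, acquisition_id=img.acquisition_id,
    )
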