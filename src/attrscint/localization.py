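"""Mask-driven crop localization with physical-unit margins.

The three predicted structure masks drive three crop strategies: bounding box
of the LV with a 70 mm margin, of the whole heart with 50 mm, and of the
ribcage with 1 mm. Margins convert to pixels by rounding ``margin_mm /
spacing`` per axis, and expanded boxes are clamped to the image. An empty
predicted mask falls back to a central thorax band (the multi-strategy
ensemble downstream further reduces the impact of a bad crop).
"""

from __future__ import annotations

import logging
from dataclasses import replace as dc_replace

import numpy as np

from .datatypes import CropRegion, LabelMask, PlanarImage
from .errors import EmptyMaskError

logger = logging.getLogger(__name__)

CROP_MARGINS_MM = {"lv": 70.0, "whole_heart": 50.0, "ribcage": 1.0}


def mask_bbox(mask: LabelMask) -> CropRegion:
    """Tightest half-open box containing all foreground pixels."""
    if mask.data.ndim != 2:
        raise ValueError("mask_bbox expects a 2D mask")
    rows = np.flatnonzero(mask.data.any(axis=1))
    cols = np.flatnonzero(mask.data.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError(f"mask {mask.structure!r} is empty")
    return CropRegion(
        row_min=int(rows[0]), row_max=int(rows[-1]) + 1,
        col_min=int(cols[0]), col_max=int(cols[-1]) + 1,
        strategy=mask.structure, margin_mm=0.0,
    )


def crop_with_margin(
    img: PlanarImage, box: CropRegion, margin_mm: float
) -> tuple[PlanarImage, CropRegion]:
    """Expand the box by a physical margin (rounded to pixels), clamp, crop."""
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    dr = round(margin_mm / img.spacing_mm[0])
    dc = round(margin_mm / img.spacing_mm[1])
    h, w = img.shape
    region = CropRegion(
        row_min=max(0, box.row_min - dr), row_max=min(h, box.row_max + dr),
        col_min=max(0, box.col_min - dc), col_max=min(w, box.col_max + dc),
        strategy=box.strategy, margin_mm=float(margin_mm),
    )
    cropped = img.with_pixels(img.pixels[region.slices()].copy())
    return cropped, region


def _fallback_region(img: PlanarImage, strategy: str) -> CropRegion:
    """Central 50%-height thorax band, full width."""
    h, w = img.shape
    return CropRegion(
        row_min=h // 4, row_max=h // 4 + max(1, h // 2),
        col_min=0, col_max=w, strategy=strategy, margin_mm=0.0,
    )


def localize_all(
    img: PlanarImage,
    masks: dict[str, LabelMask],
    margins_mm: dict[str, float] | None = None,
    return_regions: bool = False,
):
    """Produce the three per-strategy crops driving classification.

    Always returns all three strategies; an empty mask triggers the central
    thorax-band fallback (logged), and if every mask is empty the full image
    is returned for all strategies with a warning.
    """
    margins = margins_mm or CROP_MARGINS_MM
    if all(masks[s].is_empty() for s in margins if s in masks):
        logger.warning(
            "all structure masks empty for %s; returning full image crops",
            img.patient_id,
        )
        full = CropRegion(0, img.shape[0], 0, img.shape[1])
        crops = {
            s: (img.with_pixels(img.pixels.copy()), dc_replace(full, strategy=s))
            for s in margins
        }
    else:
        crops = {}
        for strategy, margin in margins.items():
            mask = masks.get(strategy)
            try:
                if mask is None:
                    raise EmptyMaskError(f"no mask for {strategy!r}")
                box = mask_bbox(mask)
            except EmptyMaskError:
                logger.warning(
                    "empty %s mask for %s; using central thorax-band fallback",
                    strategy, img.patient_id,
                )
                box = _fallback_region(img, strategy)
                margin = 0.0
            crops[strategy] = crop_with_margin(img, box, margin)
    if return_regions:
        return crops
    return {s: c[0] for s, c in crops.items()}
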