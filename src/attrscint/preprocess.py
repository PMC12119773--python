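"""Intensity normalization and summation-image construction.

Planar scintigraphy is not quantitative: counts depend on acquisition time,
injected activity and post-injection delay. Every image is therefore
normalized to its own 99th percentile (rather than its maximum, to be robust to
isolated hot noise pixels), clipping to [0, P99] and dividing by P99. The
summation image adds the anterior view and the left-right mirrored posterior
view to improve counting statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import PlanarImage
from .errors import AlignmentError


@dataclass
class NormalizationSpec:
    percentile: float = 99.0
    clip_low: float = 0.0

    def __post_init__(self):
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")


def percentile_normalize(
    img: PlanarImage, spec: NormalizationSpec | None = None
) -> PlanarImage:
    """Clip to [0, P] and divide by P, P the image's own percentile (default 99).

    Uses the linear-interpolation quantile over all pixels. Raises on an
    all-zero image, where the scale is undefined.
    """
    spec = spec or NormalizationSpec()
    p = float(np.percentile(img.pixels, spec.percentile))
    if p <= 0:
        raise ValueError("cannot normalize: percentile of image is zero")
    out = np.clip(img.pixels, spec.clip_low, p) / p
    return img.with_pixels(out)


def make_summation(anterior: PlanarImage, posterior: PlanarImage) -> PlanarImage:
    """Anterior + left-right mirrored posterior, tagged as the summation view."""
    if anterior.view != "anterior" or posterior.view != "posterior":
        raise ValueError("inputs must be the anterior and posterior views")
    if anterior.shape != posterior.shape:
        raise AlignmentError("anterior/posterior shape mismatch")
    if anterior.spacing_mm != posterior.spacing_mm:
        raise AlignmentError("anterior/posterior spacing mismatch")
    pixels = anterior.pixels + posterior.pixels[:, ::-1]
    return PlanarImage(
        pixels,
        spacing_mm=anterior.spacing_mm,
        view="summation",
        patient_id=anterior.patient_id,
        acquisition_id=anterior.acquisition_id,
    )
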