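"""Saliency maps: GradCAM mechanics, occlusion sensitivity, overlays."""

import numpy as np
import pytest

from attrscint._nn import Conv2D, Dense, GlobalAvgPool, ReLU, Sequential
from attrscint.explain import (
    SaliencyMap,
    gradcam,
    occlusion_sensitivity,
    threshold_overlay,
)


def _identity_probe():
    """Conv stage passes the image through; score 1 = mean of the activations."""
    rng = np.random.default_rng(0)
    conv = Conv2D(1, 1, 1, rng)
    conv.W[...] = 1.0
    conv.b[...] = 0.0
    dense = Dense(1, 2, rng)
    dense.W[...] = np.array([[0.0, 1.0]])
    dense.b[...] = 0.0
    return Sequential([conv, ReLU(), GlobalAvgPool(), dense])


def test_gradcam_of_linear_probe_follows_input_mass():
    """For a linear region-mean score, the channel weight is the (positive)
    pooled gradient, so the cam is proportional to the activation map: a bright
    rectangle holds the corresponding share of the saliency mass."""
    net = _identity_probe()
    img = np.full((24, 24), 0.05)
    img[8:16, 6:14] = 1.0  # bright region carrying most of the input mass
    smap = gradcam(net, img, target_class=1)
    assert smap.values.shape == img.shape
    inside = smap.values[8:16, 6:14].sum()
    assert inside / smap.values.sum() >= 0.8


def test_gradcam_constant_model_is_flat():
    net = _identity_probe()
    smap = gradcam(net, np.zeros((16, 16)), target_class=1)
    np.testing.assert_array_equal(smap.values, 0.0)


def test_gradcam_rescaled_to_unit_max():
    net = _identity_probe()
    rng = np.random.default_rng(1)
    smap = gradcam(net, rng.uniform(size=(16, 16)), target_class=1)
    assert smap.values.max() == pytest.approx(1.0)
    assert smap.values.min() >= 0.0


def test_gradcam_rejects_model_without_spatial_activations():
    rng = np.random.default_rng(2)
    net = Sequential([GlobalAvgPool(), Dense(1, 2, rng)])
    with pytest.raises(ValueError, match="spatial"):
        gradcam(net, np.ones((8, 8)), target_class=0)


class PixelReader:
    """Score driven by a single pixel: prob drop localizes exactly there."""

    def __init__(self, r, c):
        self.r, self.c = r, c

    def forward(self, x, cache=False):
        v = x[:, 0, self.r, self.c]
        return np.stack([np.zeros_like(v), 4.0 * v], axis=1)


def test_occlusion_peaks_on_windows_covering_the_read_pixel():
    model = PixelReader(10, 12)
    img = np.ones((24, 24))
    smap = occlusion_sensitivity(model, img, target_class=1,
                                 patch_hw=(4, 4), stride=2)
    assert smap.values[10, 12] == smap.values.max() == 1.0
    far = smap.values[:4, :4]
    np.testing.assert_array_equal(far, 0.0)


def test_occlusion_constant_model_is_flat():
    class Flat:
        def forward(self, x, cache=False):
            return np.tile([1.0, -1.0], (x.shape[0], 1))

    smap = occlusion_sensitivity(Flat(), np.ones((16, 16)), 0, (4, 4), 4)
    np.testing.assert_array_equal(smap.values, 0.0)


def test_occlusion_stride_equals_patch_tiles_disjointly():
    model = PixelReader(3, 3)
    smap = occlusion_sensitivity(model, np.ones((16, 16)), 1, (4, 4), 4)
    # every pixel covered exactly once: drop localized to one 4x4 tile
    assert smap.values[0:4, 0:4].min() == 1.0
    assert smap.values[4:, :].max() == 0.0


def test_occlusion_rejects_patch_geq_image():
    with pytest.raises(ValueError):
        occlusion_sensitivity(PixelReader(0, 0), np.ones((8, 8)), 0, (8, 8), 2)


def test_threshold_overlay_extremes_and_oracle():
    rng = np.random.default_rng(3)
    values = rng.uniform(size=(12, 12))
    values[0, 0], values[-1, -1] = 0.0, 1.0
    smap = SaliencyMap(values, "gradcam", 1)
    assert threshold_overlay(smap, 0.0).data.all()
    top = threshold_overlay(smap, 1.0).data
    np.testing.assert_array_equal(top, values >= 1.0)
    half = threshold_overlay(smap, 0.5).data
    np.testing.assert_array_equal(half, values >= 0.5)
    with pytest.raises(ValueError):
        threshold_overlay(smap, 1.5)


def test_saliency_focuses_on_heart_for_trained_classifier(
    detection_model, separable_cohort,
):
    """An uptake-driven classifier attends to the cardiac region of grade-3
    crops: the occlusion-sensitivity peak falls on the (dilated) projected
    heart in every case, and GradCAM mass inside the heart is at least twice
    what a uniform map would put there. The heart occupies only a few percent
    of the crop, so per-image P99 normalization leaves the background level
    itself class-informative and saliency never concentrates entirely on the
    heart; enrichment plus peak location is the discriminating check."""
    from scipy import ndimage

    from attrscint.classification import prepare_crop
    from attrscint.datatypes import PlanarImage
    from attrscint.localization import crop_with_margin, mask_bbox

    model, _, _ = detection_model
    enrichment, peak_on_heart = [], []
    for case in separable_cohort:
        if case.grade != 3:
            continue
        heart = case.masks["whole_heart"]
        box = mask_bbox(heart)
        img = case.images["anterior"]
        crop, region = crop_with_margin(img, box, 50.0)
        heart_crop = heart.data[region.slices()]
        x = prepare_crop(crop, model.cfg)
        # map the heart mask through the same letterbox geometry
        mask_img = PlanarImage(heart_crop.astype(float), img.spacing_mm)
        m = prepare_crop(mask_img, model.cfg) > 0.25
        smap = gradcam(model, x, target_class=1)
        if smap.values.sum() > 0:
            frac = smap.values[m].sum() / smap.values.sum()
            enrichment.append(frac / m.mean())
        occ = occlusion_sensitivity(model, x, 1, (16, 16), 8)
        peak = np.unravel_index(occ.values.argmax(), occ.values.shape)
        peak_on_heart.append(ndimage.binary_dilation(m, iterations=8)[peak])
    assert enrichment, "no grade-3 cases in fixture cohort"
    assert np.mean(enrichment) >= 2.0
    assert all(peak_on_heart)
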