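"""Crop localization: bounding boxes, physical margins, fallbacks."""

import numpy as np
import pytest

from attrscint.datatypes import LabelMask, PhantomSpec, PlanarImage
from attrscint.errors import EmptyMaskError
from attrscint.localization import crop_with_margin, localize_all, mask_bbox
from attrscint.phantom import generate_phantom
from attrscint.preprocess import percentile_normalize
from attrscint.projection import project_mask, project_volume


def _mask(shape, coords, structure="whole_heart"):
    m = np.zeros(shape, bool)
    for r, c in coords:
        m[r, c] = True
    return LabelMask(m, structure, (2.8, 2.8))


def test_bbox_single_pixel():
    box = mask_bbox(_mask((10, 10), [(5, 7)]))
    assert (box.row_min, box.row_max, box.col_min, box.col_max) == (5, 6, 7, 8)


def test_bbox_full_mask():
    box = mask_bbox(LabelMask(np.ones((6, 8), bool), "lv", (2.8, 2.8)))
    assert (box.row_min, box.row_max, box.col_min, box.col_max) == (0, 6, 0, 8)


def test_bbox_matches_index_scan_oracle():
    rng = np.random.default_rng(0)
    m = rng.uniform(size=(20, 24)) < 0.05
    m[3, 4] = True  # guarantee non-empty
    box = mask_bbox(LabelMask(m, "ribcage", (2.8, 2.8)))
    rows, cols = np.nonzero(m)
    assert (box.row_min, box.row_max) == (rows.min(), rows.max() + 1)
    assert (box.col_min, box.col_max) == (cols.min(), cols.max() + 1)


def test_bbox_empty_mask_signals():
    with pytest.raises(EmptyMaskError):
        mask_bbox(LabelMask(np.zeros((5, 5), bool), "lv", (2.8, 2.8)))


def test_margin_70mm_at_2p8mm_expands_25_pixels():
    img = PlanarImage(np.ones((128, 128)), spacing_mm=(2.8, 2.8))
    box = mask_bbox(_mask((128, 128), [(60, 60), (70, 72)]))
    _, region = crop_with_margin(img, box, 70.0)
    assert region.row_min == 60 - 25 and region.row_max == 71 + 25
    assert region.col_min == 60 - 25 and region.col_max == 73 + 25


def test_margin_zero_is_tight_bbox():
    img = PlanarImage(np.arange(64, dtype=float).reshape(8, 8))
    box = mask_bbox(_mask((8, 8), [(2, 3), (4, 5)]))
    cropped, region = crop_with_margin(img, box, 0.0)
    np.testing.assert_array_equal(cropped.pixels, img.pixels[2:5, 3:6])
    assert region.shape == (3, 3)


def test_margin_clamped_at_corner():
    img = PlanarImage(np.ones((32, 32)), spacing_mm=(2.8, 2.8))
    box = mask_bbox(_mask((32, 32), [(0, 0)]))
    _, region = crop_with_margin(img, box, 200.0)
    assert (region.row_min, region.col_min) == (0, 0)
    assert region.row_max <= 32 and region.col_max <= 32


def test_localize_all_crops_contain_true_heart_bbox():
    vol, anat = generate_phantom(PhantomSpec(grid_shape=(96, 96, 96), seed=5))
    img = percentile_normalize(project_volume(vol))
    masks = {s: project_mask(anat[s]) for s in anat.masks}
    heart_box = mask_bbox(masks["whole_heart"])
    crops = localize_all(img, masks, return_regions=True)
    assert set(crops) == {"lv", "whole_heart", "ribcage"}
    for strategy, (crop, region) in crops.items():
        assert region.row_min <= heart_box.row_min
        assert region.row_max >= heart_box.row_max
        assert region.col_min <= heart_box.col_min
        assert region.col_max >= heart_box.col_max


def test_localize_all_containment_of_driving_mask():
    rng = np.random.default_rng(1)
    img = PlanarImage(rng.uniform(size=(64, 64)), spacing_mm=(2.8, 2.8))
    masks = {
        "lv": _mask((64, 64), [(30, 30), (34, 33)], "lv"),
        "whole_heart": _mask((64, 64), [(28, 28), (36, 36)], "whole_heart"),
        "ribcage": _mask((64, 64), [(10, 5), (50, 58)], "ribcage"),
    }
    crops = localize_all(img, masks, return_regions=True)
    for s, (crop, region) in crops.items():
        tight = mask_bbox(masks[s])
        assert region.row_min <= tight.row_min and region.row_max >= tight.row_max
        assert region.col_min <= tight.col_min and region.col_max >= tight.col_max


def test_localize_all_empty_lv_falls_back(caplog):
    rng = np.random.default_rng(2)
    img = PlanarImage(rng.uniform(size=(64, 64)), spacing_mm=(2.8, 2.8))
    masks = {
        "lv": LabelMask(np.zeros((64, 64), bool), "lv", (2.8, 2.8)),
        "whole_heart": _mask((64, 64), [(28, 28), (36, 36)], "whole_heart"),
        "ribcage": _mask((64, 64), [(10, 5), (50, 58)], "ribcage"),
    }
    with caplog.at_level("WARNING"):
        crops = localize_all(img, masks, return_regions=True)
    # fallback: central 50%-height band, full width
    _, region = crops["lv"]
    assert (region.row_min, region.row_max) == (16, 48)
    assert (region.col_min, region.col_max) == (0, 64)
    assert "fallback" in caplog.text


def test_localize_all_every_mask_empty_returns_full_image(caplog):
    img = PlanarImage(np.ones((32, 32)), spacing_mm=(2.8, 2.8))
    empty = {
        s: LabelMask(np.zeros((32, 32), bool), s, (2.8, 2.8))
        for s in ("lv", "whole_heart", "ribcage")
    }
    with caplog.at_level("WARNING"):
        crops = localize_all(img, empty, return_regions=True)
    for s, (crop, region) in crops.items():
        assert crop.shape == (32, 32)
    assert "full image" in caplog.text


def test_full_masks_give_clamped_full_image():
    img = PlanarImage(np.ones((32, 32)), spacing_mm=(2.8, 2.8))
    full = {
        s: LabelMask(np.ones((32, 32), bool), s, (2.8, 2.8))
        for s in ("lv", "whole_heart", "ribcage")
    }
    crops = localize_all(img, full)
    for s, crop in crops.items():
        assert crop.shape == (32, 32)


def test_bright_extraneous_blob_does_not_displace_heart_crop(
    heart_segmenter_augmented,
):
    """Robustness surrogate for contamination (urine-bag-like hot spot): the
    whole-heart crop center must not move by more than the 50 mm margin."""
    from attrscint.segmentation import sliding_window_segment

    vol, anat = generate_phantom(PhantomSpec(grid_shape=(96, 96, 96), seed=77))
    img = project_volume(vol)
    blobbed = img.pixels.copy()
    blobbed[80:88, 60:68] = blobbed.max() * 3.0  # pelvic hot spot
    clean = percentile_normalize(img)
    dirty = percentile_normalize(img.with_pixels(blobbed))

    def center(image):
        mask = sliding_window_segment(heart_segmenter_augmented, image, None)
        crops = localize_all(
            image, {"whole_heart": mask,
                    "lv": mask, "ribcage": mask},
            return_regions=True,
        )
        r = crops["whole_heart"][1]
        return np.array([(r.row_min + r.row_max) / 2, (r.col_min + r.col_max) / 2])

    shift_px = np.abs(center(clean) - center(dirty)).max()
    assert shift_px <= 50.0 / 2.8
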