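"""Shared fixtures: small phantoms and trained desk-scale models.

Heavy fixtures (trained networks) are session-scoped so several tests can
share one training run. Everything is seeded; phantom grids are 96^3 at 2.8 mm
(physical extent ~27 cm) unless a test needs something smaller.
"""

from __future__ import annotations

import numpy as np
import pytest

from attrscint.augment import UptakeLevelScheme, expand_case
from attrscint.classification import (
    ClsTrainConfig,
    TaskSpec,
    assign_task_label,
    prepare_crop,
    train_classifier,
)
from attrscint.datatypes import PhantomSpec
from attrscint.localization import localize_all
from attrscint.phantom import generate_cohort, generate_phantom
from attrscint.preprocess import percentile_normalize
from attrscint.projection import project_mask, project_volume
from attrscint.segmentation import SegTrainConfig, train_segmenter

GRID = (96, 96, 96)


def phantom_pairs(n, seed, structure="whole_heart", uptake=0.0, with_lv=False):
    """(normalized image, structure mask[, lv mask]) pairs from seeded phantoms."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = PhantomSpec(
            grid_shape=GRID, cardiac_uptake_fraction=uptake,
            seed=int(rng.integers(2**31)),
        )
        vol, anat = generate_phantom(spec)
        img = project_volume(vol)
        mask = project_mask(anat[structure])
        if with_lv:
            out.append((img, mask, project_mask(anat["lv"])))
        else:
            out.append((percentile_normalize(img), mask))
    return out


@pytest.fixture(scope="session")
def heart_segmenter_augmented():
    """Whole-heart segmenter trained on uptake-augmented phantom projections."""
    raw = phantom_pairs(10, seed=101, with_lv=True)
    scheme = UptakeLevelScheme(0.25, 1.5, 0.25, 6)
    train = []
    for i, (img, mask, lv) in enumerate(raw):
        for case in expand_case(img, lv, scheme, seed=500 + i):
            train.append((percentile_normalize(case.image), mask))
    val = phantom_pairs(4, seed=102)
    cfg = SegTrainConfig.desk(epochs=4, seed=0)
    model, history = train_segmenter(train, val, cfg)
    return model


@pytest.fixture(scope="session")
def separable_cohort():
    """16 patients, grades 0 and 3 only, with true projected masks."""
    return generate_cohort(
        16, (0.5, 0.0, 0.0, 0.5), PhantomSpec(grid_shape=GRID), seed=7,
        with_masks=True,
    )


@pytest.fixture(scope="session")
def cohort_crop_items(separable_cohort):
    """(prepared whole-heart crop, detection label, patient id) per case."""
    cfg = ClsTrainConfig.desk(seed=0)
    task = TaskSpec.detection()
    items = []
    for c in separable_cohort:
        crops = localize_all(c.images["anterior"], c.masks)
        x = prepare_crop(crops["whole_heart"], cfg)
        items.append((x, assign_task_label(c.grade, task), c.patient_id))
    return items


@pytest.fixture(scope="session")
def detection_model(cohort_crop_items):
    """cnn_small trained on separable whole-heart crops (grade 0 vs 3)."""
    cfg = ClsTrainConfig.desk(seed=0)
    task = TaskSpec.detection()
    pos = [(x, y) for x, y, _ in cohort_crop_items if y == 1]
    neg = [(x, y) for x, y, _ in cohort_crop_items if y == 0]
    train = pos[:-4] + neg[:-4]
    val = pos[-4:-2] + neg[-4:-2]  # last two of each class left for testing
    model, history = train_classifier(train, val, task, cfg)
    return model, history, (train, val)
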