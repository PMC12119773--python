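"""End-to-end orchestration: simulate -> segment -> crop -> classify -> ensemble.

The in-memory pipeline mirrors the clinical workflow: three single-structure
segmenters localize the heart on the summation image; three crop strategies
(LV + 70 mm, whole heart + 50 mm, ribcage + 1 mm) are applied to the anterior,
posterior and summation views; for each task a classifier is trained per
(fold, crop, view) cell of the patient-wise 3-fold grid (27 models); each test
case is scored by two-stage probability averaging over the models that never
saw it.

Crops for the posterior view use the left-right mirrored masks, since the
posterior acquisition is mirrored relative to the anterior frame.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .augment import balance_classes
from .classification import (
    ClsTrainConfig,
    TaskSpec,
    assign_task_label,
    patientwise_folds,
    predict_proba,
    prepare_crop,
    train_classifier,
)
from .datatypes import LabeledCase, LabelMask, PhantomSpec, PlanarImage
from .ensemble import MetricsReport, compute_metrics, two_stage_ensemble
from .localization import localize_all
from .phantom import generate_cohort, generate_phantom
from .preprocess import make_summation, percentile_normalize
from .projection import project_mask, project_volume
from .segmentation import SegTrainConfig, SegModel, sliding_window_segment, train_segmenter

logger = logging.getLogger(__name__)

STRATEGIES = ("lv", "whole_heart", "ribcage")
INPUT_VIEWS = ("anterior", "posterior", "summation")


def make_segmentation_pairs(
    n: int,
    spec_template: PhantomSpec,
    seed: int,
    structure: str,
    *,
    uptake_levels: tuple[float, ...] = (),
    normalize: bool = True,
) -> list[tuple[PlanarImage, LabelMask]]:
    """Pseudo-planar (image, mask) training pairs from grade-0 phantoms.

    ``uptake_levels`` optionally augments each phantom with simulated cardiac
    uptake at the given fractions via :func:`attrscint.augment.expand_case`
    semantics (original always included).
    """
    from .augment import simulate_uptake

    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        spec = dataclasses.replace(
            spec_template, cardiac_uptake_fraction=0.0, seed=int(rng.integers(2**31))
        )
        vol, anat = generate_phantom(spec)
        img = project_volume(vol)
        mask = project_mask(anat[structure])
        lv2d = project_mask(anat["lv"])
        images = [img]
        for f in uptake_levels:
            images.append(
                simulate_uptake(img, lv2d, f, int(rng.integers(2**31))).image
            )
        for im in images:
            pairs.append((percentile_normalize(im) if normalize else im, mask))
    return pairs


def train_all_segmenters(
    spec_template: PhantomSpec,
    seed: int,
    *,
    n_train: int = 10,
    n_val: int = 4,
    uptake_levels: tuple[float, ...] = (0.3, 0.7, 1.1, 1.5),
    cfg: SegTrainConfig | None = None,
) -> dict[str, SegModel]:
    """One uptake-augmented segmenter per structure (lv, whole_heart, ribcage)."""
    models = {}
    for i, structure in enumerate(STRATEGIES):
        train = make_segmentation_pairs(
            n_train, spec_template, seed + 11 * i, structure,
            uptake_levels=uptake_levels,
        )
        val = make_segmentation_pairs(
            n_val, spec_template, seed + 11 * i + 5, structure,
            uptake_levels=uptake_levels[:1],
        )
        c = cfg or SegTrainConfig.desk(epochs=6, seed=seed + i)
        models[structure], hist = train_segmenter(train, val, c)
        logger.info(
            "segmenter %s best val dice %.3f", structure,
            max(h["val_dice"] for h in hist),
        )
    return models


def segment_case(case: LabeledCase, seg_models: dict[str, SegModel]) -> dict[str, LabelMask]:
    """Predict the three structure masks on the case's summation image."""
    summation = make_summation(case.images["anterior"], case.images["posterior"])
    img = percentile_normalize(summation)
    return {
        s: sliding_window_segment(m, img, m.cfg.patch_hw)
        for s, m in seg_models.items()
    }


def build_crop_inputs(
    case: LabeledCase,
    masks: dict[str, LabelMask],
    cls_cfg: ClsTrainConfig,
) -> dict[tuple[str, str], np.ndarray]:
    """Prepared classifier inputs for every (crop strategy, view) combination."""
    summation = make_summation(case.images["anterior"], case.images["posterior"])
    views = {
        "anterior": case.images["anterior"],
        "posterior": case.images["posterior"],
        "summation": summation,
    }
    mirrored = {
        s: LabelMask(m.data[:, ::-1].copy(), m.structure, m.spacing_mm)
        for s, m in masks.items()
    }
    out = {}
    for view_name, img in views.items():
        vmasks = mirrored if view_name == "posterior" else masks
        crops = localize_all(img, vmasks)
        for strategy, crop in crops.items():
            out[(strategy, view_name)] = prepare_crop(crop, cls_cfg)
    return out


def run_classification_cv(
    cases: list[LabeledCase],
    crop_inputs: dict[str, dict[tuple[str, str], np.ndarray]],
    task: TaskSpec,
    cls_cfg: ClsTrainConfig,
    seed: int,
    *,
    k: int = 3,
    balance: bool = True,
) -> tuple[MetricsReport, dict]:
    """Patient-wise k-fold cross-validation of the full model grid for one task.

    Trains k x 3 crops x 3 views models. Each case is scored by the two-stage
    ensemble of the 9 models from the fold in which the case was held out, so
    no prediction uses a model that trained on that patient.
    """
    fold_of = patientwise_folds(cases, k=k, seed=seed)
    labels = {c.patient_id: assign_task_label(c.grade, task) for c in cases}
    models = {}
    rng = np.random.default_rng(seed)

    for fold in range(k):
        trainval = [c for c in cases if fold_of[c.patient_id] != fold]
        # patient-wise, label-stratified ~80/20 train/validation split
        pats = sorted({c.patient_id for c in trainval})
        pats = [pats[i] for i in rng.permutation(len(pats))]
        val_p, train_p = set(), set()
        for lab in (0, 1):
            group = [p for p in pats if labels[p] == lab]
            if len(group) < 2:
                raise ValueError(
                    f"fold {fold}: need >= 2 patients of task class {lab} "
                    "in the training folds"
                )
            n_val = max(1, len(group) // 5)
            val_p.update(group[:n_val])
            train_p.update(group[n_val:])
        for strategy in STRATEGIES:
            for view in INPUT_VIEWS:
                def grab(pids):
                    return [
                        (crop_inputs[c.patient_id][(strategy, view)],
                         labels[c.patient_id])
                        for c in trainval if c.patient_id in pids
                    ]
                tr, va = grab(train_p), grab(val_p)
                if balance:
                    counts = np.bincount([y for _, y in tr], minlength=2)
                    target = int(counts.max())
                    tr_imgs = [
                        (PlanarImage(x, view="pseudo"), y) for x, y in tr
                    ]
                    tr_bal = balance_classes(
                        tr_imgs, target, int(rng.integers(2**31))
                    )
                    tr = [(img.pixels, y) for img, y in tr_bal]
                cfg = dataclasses.replace(cls_cfg, seed=int(rng.integers(2**31)))
                model, _ = train_classifier(
                    tr, va, task, cfg, provenance=(fold, strategy, view)
                )
                models[(fold, strategy, view)] = model

    # held-out predictions: each case scored by its own test fold's 9 models
    y_true, probs = [], []
    for c in cases:
        fold = fold_of[c.patient_id]
        grid = {
            (fold, s, v): predict_proba(
                models[(fold, s, v)], crop_inputs[c.patient_id][(s, v)]
            )
            for s in STRATEGIES for v in INPUT_VIEWS
        }
        result = two_stage_ensemble(grid)
        probs.append(result.averaged_p)
        y_true.append(labels[c.patient_id])
    report = compute_metrics(y_true, probs)
    return report, {"models": models, "fold_of": fold_of,
                    "probs": probs, "labels": y_true}


def run_end_to_end(
    n_patients: int = 60,
    seed: int = 0,
    *,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    grade_proportions=(0.25, 0.25, 0.25, 0.25),
    seg_cfg: SegTrainConfig | None = None,
    cls_cfg: ClsTrainConfig | None = None,
    tasks: tuple[TaskSpec, ...] = (TaskSpec.detection(), TaskSpec.severity()),
) -> dict[str, MetricsReport]:
    """Full pipeline on a synthetic cohort; returns a MetricsReport per task."""
    spec = PhantomSpec(grid_shape=grid_shape)
    cases = generate_cohort(n_patients, grade_proportions, spec, seed)
    seg_models = train_all_segmenters(spec, seed + 1000, cfg=seg_cfg)
    cls_cfg = cls_cfg or ClsTrainConfig.desk()
    crop_inputs = {
        c.patient_id: build_crop_inputs(c, segment_case(c, seg_models), cls_cfg)
        for c in cases
    }
    reports = {}
    for task in tasks:
        report, _ = run_classification_cv(
            cases, crop_inputs, task, cls_cfg, seed + 2000
        )
        reports[task.name] = report
        logger.info("task %s: AUC=%.3f BAC=%.3f", task.name, report.auc, report.bac)
    return reports
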