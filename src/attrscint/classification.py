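"""Binary classification of cropped planar views.

Two tasks share one machinery: *detection* separates Perugini grade 0 from
grades 1-3, *severity* separates grades 0-1 from grades 2-3. Training is
patient-wise 3-fold cross-validated; every epoch records F1, sensitivity, AUC,
specificity and accuracy on the validation split, and the checkpoint
maximizing their unweighted mean is kept (ties resolve to the earlier epoch).

Inputs are crops resampled to 2.8 mm pixels, P99-normalized, and letterboxed
(zero-padded, downscaled only when larger) to a fixed network input size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as sk_resize
from sklearn.metrics import roc_auc_score

from ._nn import Adam, Sequential, make_small_cnn, softmax, softmax_cross_entropy
from .datatypes import ClassProbabilities, LabeledCase, PlanarImage
from .preprocess import percentile_normalize
from .projection import resample_2d

VAL_METRICS = ("f1", "sensitivity", "auc", "specificity", "accuracy")


@dataclass(frozen=True)
class TaskSpec:
    name: str
    positive_grades: frozenset[int]

    def __post_init__(self):
        if not self.positive_grades or not self.positive_grades <= {0, 1, 2, 3}:
            raise ValueError("positive_grades must be a nonempty subset of {0..3}")

    @classmethod
    def detection(cls) -> "TaskSpec":
        return cls("detection", frozenset({1, 2, 3}))

    @classmethod
    def severity(cls) -> "TaskSpec":
        return cls("severity", frozenset({2, 3}))


def assign_task_label(grade: int, task: TaskSpec) -> int:
    """1 iff the grade belongs to the task's positive set."""
    if grade not in (0, 1, 2, 3):
        raise ValueError("grade must be in {0,1,2,3}")
    return int(grade in task.positive_grades)


def patientwise_folds(
    cases: list[LabeledCase], k: int = 3, seed: int = 0
) -> dict[str, int]:
    """Random partition of patients into k folds; all of a patient's
    acquisitions share the patient's fold."""
    patients = sorted({c.patient_id for c in cases})
    if len(patients) < k:
        raise ValueError(f"need at least {k} distinct patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[patients[idx]] = pos % k
    return assignment


@dataclass
class ClsTrainConfig:
    backbone: str = "cnn_small"
    epochs: int = 200
    batch_size: int = 8
    lr0: float = 1e-4
    lr_decay: float = 0.95
    lr_step_epochs: int = 5
    input_spacing_mm: float = 2.8
    input_hw: tuple[int, int] = (96, 96)
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("cnn_small", "densenet201"):
            raise ValueError("backbone must be 'cnn_small' or 'densenet201'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")

    @classmethod
    def desk(cls, **overrides) -> "ClsTrainConfig":
        """Small-problem defaults: few epochs, larger learning rate."""
        kw = dict(epochs=20, batch_size=4, lr0=5e-3)
        kw.update(overrides)
        return cls(**kw)


def prepare_crop(img: PlanarImage, cfg: ClsTrainConfig) -> np.ndarray:
    """Resample to the model spacing, normalize to [0,1], letterbox to input size.

    Crops larger than the input grid are downscaled preserving aspect ratio;
    smaller ones are centered in a zero background.
    """
    img = resample_2d(img, (cfg.input_spacing_mm, cfg.input_spacing_mm))
    pixels = percentile_normalize(img).pixels
    th, tw = cfg.input_hw
    h, w = pixels.shape
    scale = min(th / h, tw / w)
    if scale < 1.0:
        nh, nw = max(1, int(h * scale)), max(1, int(w * scale))
        pixels = sk_resize(pixels, (nh, nw), order=1, anti_aliasing=True)
        pixels = np.clip(pixels, 0, None)
        h, w = nh, nw
    out = np.zeros((th, tw))
    r0, c0 = (th - h) // 2, (tw - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = pixels
    return out


@dataclass
class ClsModel:
    """A trained binary classifier with its provenance (fold, crop, view)."""

    net: Sequential
    task: TaskSpec
    cfg: ClsTrainConfig
    provenance: tuple = (0, "whole_heart", "anterior")
    best_state: list = field(repr=False, default=None)

    def logits(self, x: np.ndarray) -> np.ndarray:
        if self.best_state is not None:
            self.net.set_state(self.best_state)
        return self.net.forward(x)


def _val_metrics(probs: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    pred = (probs[:, 1] > probs[:, 0]).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    acc = (tp + tn) / len(labels)
    auc = float(roc_auc_score(labels, probs[:, 1]))
    return {"f1": f1, "sensitivity": sens, "auc": auc,
            "specificity": spec, "accuracy": acc}


def train_classifier(
    train: list[tuple[np.ndarray, int]],
    val: list[tuple[np.ndarray, int]],
    task: TaskSpec,
    cfg: ClsTrainConfig,
    provenance: tuple = (0, "whole_heart", "anterior"),
) -> tuple[ClsModel, list[dict]]:
    """Train a binary classifier on prepared crops; keep the best-mean-metric epoch.

    ``train``/``val`` items are (prepared 2D array, binary label). Both splits
    must contain both classes (balance first if needed).
    """
    ytr = np.array([y for _, y in train])
    yva = np.array([y for _, y in val])
    for name, y in (("train", ytr), ("val", yva)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} split contains a single class; balance first")
    if cfg.backbone != "cnn_small":
        raise NotImplementedError(
            "only the 'cnn_small' backbone is available in this build"
        )

    xtr = np.stack([x for x, _ in train])[:, None]
    xva = np.stack([x for x, _ in val])[:, None]
    rng = np.random.default_rng(cfg.seed)
    net = make_small_cnn(rng)
    opt = Adam(net, lr=cfg.lr0)

    history: list[dict] = []
    best_mean = -np.inf
    best_state = net.get_state()
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr0 * cfg.lr_decay ** (epoch // cfg.lr_step_epochs)
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(xtr[idx])
            loss, dlogits = softmax_cross_entropy(logits, ytr[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        probs = softmax(net.forward(xva))
        metrics = _val_metrics(probs, yva)
        metrics["epoch"] = epoch
        metrics["loss"] = float(np.mean(losses))
        history.append(metrics)
        mean_metric = float(np.mean([metrics[m] for m in VAL_METRICS]))
        if mean_metric > best_mean:  # strict: ties keep the earlier epoch
            best_mean = mean_metric
            best_state = net.get_state()

    model = ClsModel(net=net, task=task, cfg=cfg, provenance=provenance,
                     best_state=best_state)
    return model, history


def best_epoch(history: list[dict]) -> int:
    """Index of the checkpointed epoch: argmax of the mean of the five metrics."""
    means = [float(np.mean([h[m] for m in VAL_METRICS])) for h in history]
    return int(np.argmax(means))


def predict_proba(model: ClsModel, img) -> ClassProbabilities:
    """Softmax class probabilities for one prepared crop (or PlanarImage)."""
    if isinstance(img, PlanarImage):
        x = prepare_crop(img, model.cfg)
    else:
        x = np.asarray(img, dtype=np.float64)
    if x.max() > 2.0:
        warnings.warn(
            "input dynamic range suggests missing P99 normalization; "
            "normalizing on the fly", stacklevel=2,
        )
        p99 = np.percentile(x, 99)
        x = np.clip(x, 0, p99) / p99
    logits = model.logits(x[None, None])
    return ClassProbabilities(softmax(logits)[0], provenance=model.provenance)
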