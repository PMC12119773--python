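"""Trainable 2D segmentation of LV, whole heart and ribcage on planar images.

Three independent single-structure models are trained on (image, mask) pairs
with a Dice + cross-entropy loss; the checkpoint with the best validation Dice
is kept. Inference tiles large images with 50%-overlap sliding windows,
averages overlapping logits and thresholds at probability 0.5.

The default desk-scale backbone is a small full-resolution convolutional
network; the full-scale transformer backbone named in the config enum requires
a GPU deep-learning stack and is not provided here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Sequential, dice_bce_loss, make_small_segnet
from .datatypes import LabelMask, PlanarImage


@dataclass
class SegTrainConfig:
    backbone: str = "unet_small"
    patch_hw: tuple[int, int] | None = (256, 704)
    epochs: int = 100
    batch_size: int = 2
    lr0: float = 1e-4
    lr_decay: float = 0.95
    lr_step_epochs: int = 5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("unet_small", "swin_unetr_v2"):
            raise ValueError("backbone must be 'unet_small' or 'swin_unetr_v2'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def desk(cls, **overrides) -> "SegTrainConfig":
        """Small-problem defaults: full-image patches, few epochs, larger lr."""
        kw = dict(patch_hw=None, epochs=10, batch_size=2, lr0=1e-2)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SegModel:
    """A trained single-structure segmenter (best-validation checkpoint)."""

    net: Sequential
    structure: str
    cfg: SegTrainConfig
    best_state: list = field(repr=False, default=None)

    def logits(self, pixels: np.ndarray) -> np.ndarray:
        """Raw logit map for one 2D image (no thresholding)."""
        if self.best_state is not None:
            self.net.set_state(self.best_state)
        out = self.net.forward(pixels[None, None].astype(np.float64))
        return out[0, 0]


def dice_score(a, b) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    da = a.data if isinstance(a, LabelMask) else np.asarray(a, dtype=bool)
    db = b.data if isinstance(b, LabelMask) else np.asarray(b, dtype=bool)
    if da.shape != db.shape:
        raise ValueError("masks must share a shape")
    sa, sb = int(da.sum()), int(db.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((da & db).sum()) / (sa + sb)


def _window_starts(length: int, patch: int, overlap: float) -> list[int]:
    """Evenly spaced window starts covering [0, length) with ~``overlap`` overlap."""
    if length <= patch:
        return [0]
    stride = patch * (1.0 - overlap)
    n = math.ceil((length - patch) / stride) + 1
    return sorted({int(round(s)) for s in np.linspace(0, length - patch, n)})


def _random_patch(img: np.ndarray, mask: np.ndarray, patch_hw, rng):
    h, w = img.shape
    ph, pw = min(patch_hw[0], h), min(patch_hw[1], w)
    r = rng.integers(0, h - ph + 1)
    c = rng.integers(0, w - pw + 1)
    return img[r : r + ph, c : c + pw], mask[r : r + ph, c : c + pw]


def train_segmenter(
    train: list[tuple[PlanarImage, LabelMask]],
    val: list[tuple[PlanarImage, LabelMask]],
    cfg: SegTrainConfig,
) -> tuple[SegModel, list[dict]]:
    """Train one single-structure segmenter; keep the best-validation-Dice epoch.

    Returns the model plus a per-epoch history of mean training loss and
    validation Dice. Deterministic for a fixed seed (single-threaded numpy).
    """
    if not train or not val:
        raise ValueError("train and val must be non-empty")
    structures = {m.structure for _, m in train} | {m.structure for _, m in val}
    if len(structures) != 1:
        raise ValueError(f"one structure per run, got {sorted(structures)}")
    structure = structures.pop()
    for img, m in list(train) + list(val):
        if img.shape != m.shape:
            raise ValueError("image/mask pairs must be aligned")
    if cfg.backbone != "unet_small":
        raise NotImplementedError(
            "only the 'unet_small' backbone is available in this build"
        )

    rng = np.random.default_rng(cfg.seed)
    net = make_small_segnet(rng)
    opt = Adam(net, lr=cfg.lr0)
    model = SegModel(net=net, structure=structure, cfg=cfg, best_state=None)

    xs = [img.pixels for img, _ in train]
    ys = [m.data for _, m in train]
    history: list[dict] = []
    best_dice = -1.0
    best_state = net.get_state()

    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr0 * cfg.lr_decay ** (epoch // cfg.lr_step_epochs)
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if cfg.patch_hw is None:
                bx = np.stack([xs[i] for i in idx])
                by = np.stack([ys[i] for i in idx])
            else:
                patches = [_random_patch(xs[i], ys[i], cfg.patch_hw, rng) for i in idx]
                bx = np.stack([p[0] for p in patches])
                by = np.stack([p[1] for p in patches])
            logits = net.forward(bx[:, None])
            loss, dlogits = dice_bce_loss(logits, by[:, None])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        # validation with current weights
        model.best_state = None
        dices = [
            dice_score(sliding_window_segment(model, img, cfg.patch_hw), m)
            for img, m in val
        ]
        val_dice = float(np.mean(dices))
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "val_dice": val_dice}
        )
        if val_dice > best_dice:  # ties keep the earlier epoch
            best_dice = val_dice
            best_state = net.get_state()

    model.best_state = best_state
    return model, history


def sliding_window_segment(
    model, img: PlanarImage, patch_hw: tuple[int, int] | None = None,
    overlap: float = 0.5, threshold: float = 0.5,
) -> LabelMask:
    """Tile, average overlapping logits, threshold at the given probability.

    Images smaller than the patch are symmetrically zero-padded and the output
    cropped back. ``patch_hw=None`` runs a single full-image window. ``model``
    needs only a ``logits(pixels) -> 2D array`` method.
    """
    pixels = img.pixels
    h, w = pixels.shape
    if patch_hw is None:
        patch_hw = (h, w)
    ph, pw = patch_hw

    pad_r, pad_c = max(0, ph - h), max(0, pw - w)
    pads = ((pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2))
    padded = np.pad(pixels, pads) if (pad_r or pad_c) else pixels
    hh, ww = padded.shape

    acc = np.zeros((hh, ww))
    cnt = np.zeros((hh, ww))
    for r in _window_starts(hh, ph, overlap):
        for c in _window_starts(ww, pw, overlap):
            acc[r : r + ph, c : c + pw] += model.logits(padded[r : r + ph, c : c + pw])
            cnt[r : r + ph, c : c + pw] += 1
    mean_logits = acc / cnt
    prob = 1.0 / (1.0 + np.exp(-mean_logits))
    out = prob >= threshold
    out = out[pads[0][0] : pads[0][0] + h, pads[1][0] : pads[1][0] + w]
    structure = getattr(model, "structure", "whole_heart")
    return LabelMask(out, structure=structure, spacing_mm=img.spacing_mm)
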