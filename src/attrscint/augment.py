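"""Amyloid-uptake data augmentation and class balancing.

The uptake augmentation expands a grade-0 (no cardiac uptake) pseudo-planar
population into a graded training set by adding a random texture inside the LV
mask, scaled so that its mean equals a chosen fraction of the base image's
99th percentile. Levels range from 5% to 150% of P99 in 5% steps; with the
default 28 levels per case plus the original, each case yields 29 images
(85 cases -> 2465 images).

``balance_classes`` is the separate photometric/geometric augmentation used to
equalize class counts before classifier training (random rotation, additive
Gaussian noise, horizontal flip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import LabelMask, PlanarImage
from .errors import AlignmentError, EmptyMaskError


@dataclass
class UptakeLevelScheme:
    """Grid of uptake fractions used for per-case expansion.

    The full grid has levels ``min_fraction, min_fraction+step, ..,
    max_fraction``; ``n_augmented_per_case`` consecutive levels starting at
    ``min_fraction`` are used (default 28, i.e. 5%..140%), and the unmodified
    original is always included, giving 29 images per case by default.
    """

    min_fraction: float = 0.05
    max_fraction: float = 1.50
    step: float = 0.05
    n_augmented_per_case: int = 28

    def __post_init__(self):
        if not self.min_fraction < self.max_fraction:
            raise ValueError("min_fraction must be < max_fraction")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.n_augmented_per_case < 0:
            raise ValueError("n_augmented_per_case must be >= 0")
        if self.n_augmented_per_case > len(self.grid()):
            raise ValueError(
                f"scheme asks for {self.n_augmented_per_case} levels but the grid "
                f"only provides {len(self.grid())}"
            )

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.max_fraction - self.min_fraction) / self.step + 1e-9)) + 1
        return self.min_fraction + self.step * np.arange(n)

    def levels(self) -> np.ndarray:
        return self.grid()[: self.n_augmented_per_case]


@dataclass
class AugmentedCase:
    """One augmented image: base + uptake of a known fraction inside the LV."""

    base: PlanarImage
    lv_mask: LabelMask
    fraction: float
    image: PlanarImage


def simulate_uptake(
    base: PlanarImage, lv_mask: LabelMask, fraction: float, seed: int
) -> AugmentedCase:
    """Add a random LV texture whose mean equals ``fraction`` x P99(base).

    The texture is i.i.d. uniform on the LV support, rescaled to the target
    mean; the level is always computed from the *base* image's P99 so repeated
    augmentation does not drift. ``fraction == 0`` returns the base unchanged.
    """
    if lv_mask.data.ndim != 2 or lv_mask.shape != base.shape:
        raise AlignmentError("lv_mask must be 2D and aligned with the base image")
    if lv_mask.is_empty():
        raise EmptyMaskError("lv_mask is empty")
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if fraction == 0:
        return AugmentedCase(base, lv_mask, 0.0, base.with_pixels(base.pixels.copy()))
    p99 = float(np.percentile(base.pixels, 99))
    rng = np.random.default_rng(seed)
    support = lv_mask.data
    tex = rng.uniform(0.5, 1.5, size=int(support.sum()))
    tex *= fraction * p99 / tex.mean()
    pixels = base.pixels.copy()
    pixels[support] += tex
    return AugmentedCase(base, lv_mask, float(fraction), base.with_pixels(pixels))


def expand_case(
    base: PlanarImage, lv_mask: LabelMask, scheme: UptakeLevelScheme, seed: int
) -> list[AugmentedCase]:
    """Original plus one augmented image per scheme level (29 total by default)."""
    ss = np.random.SeedSequence(seed)
    levels = scheme.levels()
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(levels))]
    out = [simulate_uptake(base, lv_mask, 0.0, seed)]
    for frac, cseed in zip(levels, child_seeds):
        out.append(simulate_uptake(base, lv_mask, float(frac), cseed))
    return out


def _augment_once(img: PlanarImage, rng, theta_max_deg: float, noise_sigma: float):
    pixels = img.pixels
    angle = rng.uniform(-theta_max_deg, theta_max_deg)
    out = ndimage.rotate(pixels, angle, reshape=False, order=1, mode="constant")
    if rng.uniform() < 0.5:
        out = out[:, ::-1]
    p99 = np.percentile(pixels, 99)
    out = out + rng.normal(0.0, noise_sigma * max(p99, 1e-12), size=out.shape)
    return img.with_pixels(np.clip(out, 0, None))


def balance_classes(
    cases: list[tuple[PlanarImage, int]],
    target_per_class: int,
    seed: int,
    *,
    theta_max_deg: float = 10.0,
    noise_sigma: float = 0.02,
) -> list[tuple[PlanarImage, int]]:
    """Equalize class counts by augmenting each class up to ``target_per_class``.

    Originals are always retained; extras are random compositions of rotation
    (up to ``theta_max_deg``), additive Gaussian noise (``noise_sigma`` relative
    to the image P99) and horizontal flip. Deterministic for a fixed seed.
    """
    by_class: dict[int, list[PlanarImage]] = {}
    for img, label in cases:
        by_class.setdefault(int(label), []).append(img)
    for label, members in by_class.items():
        if not members:
            raise ValueError(f"class {label} has no cases")
    max_n = max(len(m) for m in by_class.values())
    if target_per_class < max_n:
        raise ValueError("target_per_class must be >= the largest class size")
    rng = np.random.default_rng(seed)
    out: list[tuple[PlanarImage, int]] = []
    for label in sorted(by_class):
        members = by_class[label]
        out.extend((img, label) for img in members)
        for _ in range(target_per_class - len(members)):
            base = members[rng.integers(len(members))]
            out.append((_augment_once(base, rng, theta_max_deg, noise_sigma), label))
    return out
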