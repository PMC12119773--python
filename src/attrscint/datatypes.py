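"""Core in-memory containers for planar scintigraphy processing.

Axis conventions
----------------
3D activity volumes use axes ``(left-right, cranio-caudal, anterior-posterior)``
with the anterior-posterior axis declared on the volume (``ap_axis``, third axis
by convention). 2D planar images use ``(row, col) = (cranio-caudal, left-right)``
with row 0 at the head; a "horizontal mirror" flips the left-right (column)
axis, which is how the posterior view relates to the anterior one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError

VIEWS = ("anterior", "posterior", "summation", "pseudo")
STRUCTURES = ("lv", "whole_heart", "ribcage")


def _as_float(a) -> np.ndarray:
    return np.asarray(a, dtype=np.float64)


@dataclass
class PlanarImage:
    """A 2D planar scintigraphy image with physical pixel spacing.

    Parameters
    ----------
    pixels:
        Nonnegative finite 2D array, rows cranio-caudal, columns left-right.
    spacing_mm:
        (row, col) pixel spacing in millimetres, strictly positive.
    view:
        One of ``anterior``, ``posterior``, ``summation``, ``pseudo``.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (2.8, 2.8)
    view: str = "pseudo"
    patient_id: str = ""
    acquisition_id: str = ""

    def __post_init__(self):
        self.pixels = _as_float(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")
        self.spacing_mm = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be strictly positive")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, view: str | None = None) -> "PlanarImage":
        return replace(self, pixels=pixels, view=self.view if view is None else view)

    def mirrored(self) -> "PlanarImage":
        """Left-right mirror (column flip)."""
        return replace(self, pixels=self.pixels[:, ::-1].copy())


@dataclass
class ActivityVolume:
    """A 3D grid of tracer counts with physical voxel spacing.

    ``ap_axis`` declares which grid axis runs anterior to posterior; pseudo-planar
    projection sums along it. By convention it is the third axis (index 2).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (2.8, 2.8, 2.8)
    ap_axis: int | None = 2

    def __post_init__(self):
        self.voxels = _as_float(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxels must be nonnegative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelMask:
    """Binary mask (2D or 3D) for one anatomical structure."""

    data: np.ndarray
    structure: str = "whole_heart"
    spacing_mm: tuple = (2.8, 2.8)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask values must be binary (0/1)")
            arr = arr.astype(bool)
        self.data = arr
        if arr.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != arr.ndim:
            raise ValueError("spacing length must match mask dimensionality")
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self):
        return self.data.shape

    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class AnatomySet:
    """The three structure masks aligned with one activity volume.

    Invariant: the left ventricle is a strict subset of the whole heart.
    """

    masks: dict[str, LabelMask]

    def __post_init__(self):
        missing = set(STRUCTURES) - set(self.masks)
        if missing:
            raise ValueError(f"missing masks for {sorted(missing)}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise AlignmentError(f"masks have mismatched shapes: {shapes}")
        lv = self.masks["lv"].data
        heart = self.masks["whole_heart"].data
        if np.any(lv & ~heart):
            raise ValueError("lv mask must be contained in whole_heart mask")
        for name, m in self.masks.items():
            if m.is_empty():
                raise ValueError(f"mask {name!r} is empty")

    def __getitem__(self, structure: str) -> LabelMask:
        return self.masks[structure]


DEFAULT_ORGAN_INTENSITIES = {
    "soft_tissue": 1.0,
    "ribcage": 8.0,
    "kidneys": 10.0,
    "bladder": 15.0,
    "heart_blood_pool": 2.0,
}


@dataclass
class PhantomSpec:
    """Parameters of one digital thorax-abdomen-pelvis phantom.

    ``cardiac_uptake_fraction`` (f) sets the mean projected LV signal to
    f x P99 of the uptake-free pseudo-planar projection; f = 0 gives a
    Perugini grade 0 phantom, f around 1.5 the most severe simulated uptake.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (2.8, 2.8, 2.8)
    organ_intensities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_INTENSITIES)
    )
    cardiac_uptake_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be a triple with each axis >= 8")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be strictly positive")
        unknown = set(self.organ_intensities) - set(DEFAULT_ORGAN_INTENSITIES)
        if unknown:
            raise ValueError(f"unknown organ keys: {sorted(unknown)}")
        for k, v in self.organ_intensities.items():
            if v < 0:
                raise ValueError(f"organ intensity {k!r} must be >= 0")
        if self.cardiac_uptake_fraction < 0:
            raise ValueError("cardiac_uptake_fraction must be >= 0")


@dataclass
class LabeledCase:
    """One synthetic patient acquisition: planar views plus its Perugini grade."""

    patient_id: str
    acquisition_id: str
    grade: int
    images: dict[str, PlanarImage]
    uptake_fraction: float = 0.0
    masks: dict[str, LabelMask] | None = None  # projected 2D masks, anterior frame

    def __post_init__(self):
        if self.grade not in (-1, 0, 1, 2, 3):  # -1 = unlabeled screening case
            raise ValueError("grade must be in {0,1,2,3} (-1 for unlabeled)")
        if "anterior" not in self.images:
            raise ValueError("at least the anterior view must be present")


@dataclass
class ClassProbabilities:
    """Softmax output of one classifier with its provenance (fold, crop, view)."""

    p: np.ndarray
    provenance: tuple | None = None

    def __post_init__(self):
        self.p = _as_float(self.p)
        if self.p.ndim != 1:
            raise ValueError("p must be a 1D probability vector")
        if np.any(self.p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {self.p.sum()}")


@dataclass
class CropRegion:
    """Half-open pixel bounds [row_min,row_max) x [col_min,col_max), 0-based."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    strategy: str = "whole_heart"
    margin_mm: float = 0.0

    def __post_init__(self):
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("crop region must be non-empty")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("crop bounds must be nonnegative")
        if self.margin_mm < 0:
            raise ValueError("margin must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_min, self.row_max), slice(self.col_min, self.col_max))
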