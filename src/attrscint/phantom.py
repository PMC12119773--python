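"""Digital phantom generation for planar scintigraphy.

The phantoms are deliberately simple parametric bodies — an elliptical-cylinder
torso with a rib/spine lattice, two kidneys, a bladder, and an ellipsoidal heart
whose myocardial (LV) shell can carry graded amyloid-like tracer uptake. They
emulate the count distribution of a bone-tracer study (uptake in bones, kidneys
and urinary bladder, mild cardiac blood pool) well enough to exercise every
downstream stage: projection, normalization, uptake augmentation, segmentation,
localization and classification.

Organ positions and sizes are expressed as fractions of the physical grid
extent, with a small seeded jitter per phantom, so the same anatomy scales to
any grid size/spacing.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datatypes import (
    ActivityVolume,
    AnatomySet,
    LabeledCase,
    LabelMask,
    PhantomSpec,
    PlanarImage,
)
from .errors import PhantomSizingError
from .projection import project_mask, project_volume

# Default per-grade cardiac uptake-fraction intervals (fractions of the
# uptake-free projection's P99). Grade 0 is exactly zero; grades 1-3 span the
# same 5-150% range used by the uptake augmentation scheme.
DEFAULT_GRADE_INTERVALS = ((0.0, 0.0), (0.1, 0.4), (0.4, 0.9), (0.9, 1.5))

# Organ geometry in fractional coordinates (u=LR, v=CC head->feet, w=AP
# anterior->posterior); (center, semi-axes) as fractions of the grid extent.
_HEART_CENTER = (0.58, 0.28, 0.40)
_HEART_SEMI = (0.11, 0.10, 0.11)
_LV_SHELL = (0.35, 0.80)  # inner/outer radius of the LV shell, heart units
_KIDNEY_CENTERS = ((0.34, 0.58, 0.62), (0.66, 0.58, 0.62))
_KIDNEY_SEMI = (0.055, 0.075, 0.055)
_BLADDER_CENTER = (0.50, 0.90, 0.50)
_BLADDER_SEMI = (0.060, 0.050, 0.060)
_RIB_PERIOD_MM = 24.0  # cranio-caudal rib spacing; ~half is bone


def _frac_grids(shape):
    """Fractional center coordinates of each voxel along each axis."""
    u = (np.arange(shape[0]) + 0.5) / shape[0]
    v = (np.arange(shape[1]) + 0.5) / shape[1]
    w = (np.arange(shape[2]) + 0.5) / shape[2]
    return u[:, None, None], v[None, :, None], w[None, None, :]


def _ellipsoid_rho2(u, v, w, center, semi):
    return (
        ((u - center[0]) / semi[0]) ** 2
        + ((v - center[1]) / semi[1]) ** 2
        + ((w - center[2]) / semi[2]) ** 2
    )


def generate_phantom(spec: PhantomSpec) -> tuple[ActivityVolume, AnatomySet]:
    """Build one phantom: activity volume plus lv/whole_heart/ribcage masks.

    Deterministic for a fixed ``spec`` (including its seed). The LV activity is
    chosen so that the mean added signal over the projected LV support equals
    ``spec.cardiac_uptake_fraction`` times the 99th percentile of the
    uptake-free pseudo-planar projection.
    """
    shape = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    u, v, w = _frac_grids(shape)

    # per-phantom anatomical jitter: small shifts and size scaling
    def jit(scale=0.02):
        return rng.uniform(-scale, scale)

    heart_c = tuple(c + jit() for c in _HEART_CENTER)
    heart_s = tuple(s * (1.0 + jit(0.08)) for s in _HEART_SEMI)
    kidney_cs = [tuple(c + jit(0.015) for c in kc) for kc in _KIDNEY_CENTERS]
    bladder_c = tuple(c + jit(0.015) for c in _BLADDER_CENTER)

    body = (((u - 0.5) / 0.46) ** 2 + ((w - 0.5) / 0.36) ** 2 <= 1.0) & (
        (v >= 0.02) & (v <= 0.98)
    )

    heart_rho2 = _ellipsoid_rho2(u, v, w, heart_c, heart_s)
    whole_heart = heart_rho2 <= 1.0
    rho = np.sqrt(heart_rho2)
    lv = (rho >= _LV_SHELL[0]) & (rho <= _LV_SHELL[1])

    spine = (((u - 0.5) / 0.045) ** 2 + ((w - 0.75) / 0.045) ** 2 <= 1.0) & (
        (v >= 0.05) & (v <= 0.95)
    )
    shell = ((u - 0.5) / 0.44) ** 2 + ((w - 0.5) / 0.34) ** 2
    y_mm = v * shape[1] * spec.spacing_mm[1]
    rib_band = np.floor(y_mm / (_RIB_PERIOD_MM / 2.0)).astype(int) % 2 == 0
    ribs = (shell >= 0.78) & (shell <= 1.0) & (v >= 0.06) & (v <= 0.46) & rib_band
    ribcage = ribs | (spine & (v <= 0.46))

    kidneys = np.zeros(shape, dtype=bool)
    for kc in kidney_cs:
        kidneys |= _ellipsoid_rho2(u, v, w, kc, _KIDNEY_SEMI) <= 1.0
    bladder = _ellipsoid_rho2(u, v, w, bladder_c, _BLADDER_SEMI) <= 1.0

    for name, m in (("heart", whole_heart), ("lv", lv), ("ribcage", ribcage),
                    ("kidneys", kidneys), ("bladder", bladder), ("body", body)):
        if not m.any():
            raise PhantomSizingError(
                f"grid {shape} too small to place organ {name!r}"
            )

    oi = {**{k: 0.0 for k in ("soft_tissue", "ribcage", "kidneys", "bladder",
                              "heart_blood_pool")}, **spec.organ_intensities}
    activity = np.zeros(shape, dtype=np.float64)
    activity[body] = oi["soft_tissue"]
    activity[spine | ribs] = oi["ribcage"]
    activity[kidneys] = oi["kidneys"]
    activity[bladder] = oi["bladder"]
    activity[whole_heart] = oi["heart_blood_pool"]

    f = spec.cardiac_uptake_fraction
    if f > 0:
        base_proj = activity.sum(axis=2)
        p99 = np.percentile(base_proj, 99)
        if p99 > 0:
            support = lv.any(axis=2)
            n_pix = int(support.sum())
            n_vox = int(lv.sum())
            activity[lv] += f * p99 * n_pix / n_vox

    vol = ActivityVolume(activity, spacing_mm=spec.spacing_mm, ap_axis=2)
    anat = AnatomySet(
        masks={
            "lv": LabelMask(lv, "lv", spec.spacing_mm),
            "whole_heart": LabelMask(whole_heart, "whole_heart", spec.spacing_mm),
            "ribcage": LabelMask(ribcage, "ribcage", spec.spacing_mm),
        }
    )
    return vol, anat


def _poisson_rescale(values: np.ndarray, total_counts: int, rng) -> np.ndarray:
    total = values.sum()
    if total <= 0:
        raise ValueError("cannot scale an all-zero image/volume to a count total")
    lam = values * (float(total_counts) / total)
    return rng.poisson(lam).astype(np.float64)


def add_counting_noise(
    vol: ActivityVolume, total_counts: int, seed: int
) -> ActivityVolume:
    """Poisson counting noise with the expected total scaled to ``total_counts``.

    Voxel values become independent Poisson draws whose means are the input
    values rescaled so that the expected sum equals ``total_counts``.
    """
    if total_counts < 1:
        raise ValueError("total_counts must be >= 1")
    rng = np.random.default_rng(seed)
    noisy = _poisson_rescale(vol.voxels, total_counts, rng)
    return ActivityVolume(noisy, spacing_mm=vol.spacing_mm, ap_axis=vol.ap_axis)


def add_planar_counting_noise(
    img: PlanarImage, total_counts: int, seed: int
) -> PlanarImage:
    """2D counterpart of :func:`add_counting_noise` for planar views."""
    if total_counts < 1:
        raise ValueError("total_counts must be >= 1")
    rng = np.random.default_rng(seed)
    return img.with_pixels(_poisson_rescale(img.pixels, total_counts, rng))


def generate_cohort(
    n_patients: int,
    grade_proportions,
    spec_template: PhantomSpec,
    seed: int,
    *,
    grade_intervals=DEFAULT_GRADE_INTERVALS,
    counts_per_view: int = 1_000_000,
    noise: bool = True,
    with_masks: bool = False,
) -> list[LabeledCase]:
    """Generate a labeled cohort of planar acquisitions.

    Each patient receives a Perugini-like grade sampled from
    ``grade_proportions`` and a cardiac uptake fraction drawn uniformly from the
    per-grade interval. Anterior views come from pseudo-planar projection of a
    per-patient phantom; the posterior view is the left-right mirror of the
    anterior with independent counting noise.
    """
    props = np.asarray(grade_proportions, dtype=float)
    if props.shape != (4,):
        raise ValueError("grade_proportions must have 4 entries")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("grade proportions must sum to 1")
    if n_patients < 4:
        raise ValueError("n_patients must be >= 4")

    rng = np.random.default_rng(seed)
    grades = rng.choice(4, size=n_patients, p=props)
    case_seeds = rng.integers(0, 2**31 - 1, size=(n_patients, 3))

    cases = []
    for i in range(n_patients):
        g = int(grades[i])
        lo, hi = grade_intervals[g]
        f = 0.0 if g == 0 else float(np.random.default_rng(case_seeds[i, 0]).uniform(lo, hi))
        spec = dataclasses.replace(
            spec_template, cardiac_uptake_fraction=f, seed=int(case_seeds[i, 0])
        )
        vol, anat = generate_phantom(spec)
        pid, aid = f"P{i:03d}", "A1"
        ant = project_volume(vol, view="anterior", patient_id=pid, acquisition_id=aid)
        post = dataclasses.replace(ant.mirrored(), view="posterior")
        if noise:
            ant = add_planar_counting_noise(ant, counts_per_view, int(case_seeds[i, 1]))
            post = add_planar_counting_noise(post, counts_per_view, int(case_seeds[i, 2]))
        masks = None
        if with_masks:
            masks = {s: project_mask(anat[s]) for s in anat.masks}
        cases.append(
            LabeledCase(
                patient_id=pid,
                acquisition_id=aid,
                grade=g,
                images={"anterior": ant, "posterior": post},
                uptake_fraction=f,
                masks=masks,
            )
        )
    return cases
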