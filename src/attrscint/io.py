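"""Readers/writers: NIfTI and 16-bit PNG planar images, volumes, cohorts.

Planar images canonically live in NIfTI (``.nii.gz``; 2D stored with a
singleton third axis and an RAS-consistent affine built from the spacing) or
16-bit PNG. Either format carries a JSON sidecar (``<path>.json``) with
spacing, view and patient/acquisition ids, which NIfTI headers and PNG chunks
cannot hold reliably. Cohorts are one image file per view plus a labels CSV
(columns: patient_id, acquisition_id, view, grade, uptake_fraction, seed;
grade -1 marks unlabeled screening cases).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import ActivityVolume, AnatomySet, LabeledCase, LabelMask, PlanarImage

LABEL_COLUMNS = ["patient_id", "acquisition_id", "view", "grade", "uptake_fraction", "seed"]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing):
        aff[i, i] = s
    return aff


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.name + ".json")


def write_planar(path, img: PlanarImage) -> None:
    """Write a planar image (.nii/.nii.gz or 16-bit .png) plus JSON sidecar.

    PNG requires integer pixel values in [0, 65535] (count images); use NIfTI
    for floating-point data. Round-trips are lossless.
    """
    path = Path(path)
    meta = {
        "spacing_mm": list(img.spacing_mm),
        "view": img.view,
        "patient_id": img.patient_id,
        "acquisition_id": img.acquisition_id,
    }
    if path.suffix == ".png":
        if np.any(img.pixels != np.round(img.pixels)) or img.pixels.max() > 65535:
            raise ValueError(
                "PNG output requires integer pixels in [0, 65535]; use NIfTI"
            )
        Image.fromarray(img.pixels.astype(np.uint16)).save(path)
    elif path.name.endswith((".nii", ".nii.gz")):
        data = img.pixels[:, :, None]
        nib.save(nib.Nifti1Image(data, _affine((*img.spacing_mm, 1.0))), path)
    else:
        raise ValueError(f"unsupported planar format: {path.name}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_planar(path) -> PlanarImage:
    """Read a planar image and its sidecar; errors name any missing metadata."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar.name}: required fields spacing_mm, view"
        )
    meta = json.loads(sidecar.read_text())
    for fieldname in ("spacing_mm", "view"):
        if fieldname not in meta:
            raise ValueError(f"sidecar {sidecar.name} missing field {fieldname!r}")
    if path.suffix == ".png":
        pixels = np.asarray(Image.open(path), dtype=np.float64)
    else:
        arr = np.asarray(nib.load(path).dataobj, dtype=np.float64)
        if arr.ndim == 3:
            if arr.shape[2] != 1:
                raise ValueError("3D NIfTI is only accepted with a singleton third axis")
            arr = arr[:, :, 0]
        pixels = arr
    if np.any(pixels < 0):
        raise ValueError("negative pixels in planar image")
    return PlanarImage(
        pixels,
        spacing_mm=tuple(meta["spacing_mm"]),
        view=meta["view"],
        patient_id=meta.get("patient_id", ""),
        acquisition_id=meta.get("acquisition_id", ""),
    )


def write_volume(path, vol: ActivityVolume) -> None:
    nib.save(nib.Nifti1Image(vol.voxels, _affine(vol.spacing_mm)), Path(path))


def read_volume(path) -> ActivityVolume:
    img = nib.load(Path(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ActivityVolume(
        np.asarray(img.dataobj, dtype=np.float64), spacing_mm=spacing, ap_axis=2
    )


def write_mask(path, mask: LabelMask) -> None:
    data = mask.data.astype(np.uint8)
    if data.ndim == 2:
        data = data[:, :, None]
        spacing = (*mask.spacing_mm, 1.0)
    else:
        spacing = mask.spacing_mm
    nib.save(nib.Nifti1Image(data, _affine(spacing)), Path(path))
    _sidecar_path(Path(path)).write_text(
        json.dumps({"structure": mask.structure, "spacing_mm": list(mask.spacing_mm)})
    )


def read_mask(path) -> LabelMask:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    arr = np.asarray(nib.load(path).dataobj)
    if arr.ndim == 3 and arr.shape[2] == 1 and len(meta["spacing_mm"]) == 2:
        arr = arr[:, :, 0]
    return LabelMask(arr > 0, structure=meta["structure"],
                     spacing_mm=tuple(meta["spacing_mm"]))


def write_anatomy(dirpath, anat: AnatomySet, prefix: str = "mask") -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    for name, mask in anat.masks.items():
        write_mask(dirpath / f"{prefix}_{name}.nii.gz", mask)


def write_cohort(dirpath, cases: list[LabeledCase], seed: int | None = None) -> Path:
    """One NIfTI per view plus labels.csv; returns the labels path."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        for view, img in case.images.items():
            fname = f"{case.patient_id}_{case.acquisition_id}_{view}.nii.gz"
            write_planar(dirpath / fname, img)
            rows.append({
                "patient_id": case.patient_id,
                "acquisition_id": case.acquisition_id,
                "view": view,
                "grade": case.grade,
                "uptake_fraction": case.uptake_fraction,
                "seed": -1 if seed is None else seed,
            })
    labels = dirpath / "labels.csv"
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(labels, index=False)
    return labels


def read_cohort(dirpath) -> list[LabeledCase]:
    dirpath = Path(dirpath)
    df = pd.read_csv(dirpath / "labels.csv")
    cases = []
    for (pid, aid), group in df.groupby(["patient_id", "acquisition_id"], sort=True):
        images = {}
        for _, row in group.iterrows():
            fname = f"{pid}_{aid}_{row['view']}.nii.gz"
            images[row["view"]] = read_planar(dirpath / fname)
        cases.append(LabeledCase(
            patient_id=str(pid), acquisition_id=str(aid),
            grade=int(group["grade"].iloc[0]),
            images=images,
            uptake_fraction=float(group["uptake_fraction"].iloc[0]),
        ))
    return cases
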