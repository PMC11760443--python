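"""File formats: NIfTI images, ROI JSON sidecars, transform JSON, tables.

ROI JSON dialect::

    {"case": "case00", "frame": "highfield",
     "rois": [{"label": "cancerous", "lesion_id": "lesion00", "slice": 0,
               "center_px": [row, col], "radius_px": 6.0},
              {"mask_path": "mask.nii", "label": ..., "lesion_id": ...}]}

Transforms are stored either as ``{"dim": 2|3, "rotation": row-major list,
"translation_mm": list}`` or as a 4x4 homogeneous matrix (nested list).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import nibabel as nib
import numpy as np
import yaml

from .geometry import ImageGeometry, RigidTransform, RoiSpec

__all__ = [
    "load_image",
    "save_image",
    "load_transform",
    "save_transform",
    "load_rois",
    "save_rois",
    "load_yaml",
    "save_yaml",
]


def save_image(path, data: np.ndarray, geometry: Optional[ImageGeometry] = None) -> None:
    """Write a 2-D slice (or 3-D volume) as NIfTI; spacing goes into the
    affine diagonal."""
    data = np.asarray(data, dtype=np.float64)
    spacing = geometry.spacing if geometry is not None else (1.0,) * data.ndim
    affine = np.eye(4)
    for ax, s in enumerate(spacing):
        affine[ax, ax] = s
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))


def load_image(path) -> tuple:
    """Read a NIfTI image; returns (data, ImageGeometry)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[: data.ndim]
    geom = ImageGeometry(data.shape, tuple(float(z) for z in zooms))
    return data, geom


def save_transform(path, T: RigidTransform) -> None:
    Path(path).write_text(json.dumps(T.to_dict(), indent=2))


def load_transform(path) -> RigidTransform:
    obj = json.loads(Path(path).read_text())
    if isinstance(obj, list):  # 4x4 homogeneous matrix
        return RigidTransform.from_homogeneous(np.asarray(obj, float))
    if "matrix" in obj:
        return RigidTransform.from_homogeneous(np.asarray(obj["matrix"], float))
    return RigidTransform.from_dict(obj)


def save_rois(path, rois: Sequence[RoiSpec], case: str = "", frame: str = "highfield") -> None:
    payload = {"case": case, "frame": frame, "rois": [r.to_dict() for r in rois]}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rois(path) -> List[RoiSpec]:
    obj = json.loads(Path(path).read_text())
    frame = obj.get("frame", "highfield")
    base = Path(path).parent
    rois = []
    for entry in obj["rois"]:
        common = dict(
            label=entry["label"],
            lesion_id=entry["lesion_id"],
            frame=frame,
            slice_index=int(entry.get("slice", 0)),
        )
        if "mask_path" in entry:
            mask, _ = load_image(base / entry["mask_path"])
            rois.append(RoiSpec("mask", mask=mask > 0.5, **common))
        elif "mask" in entry:
            rois.append(RoiSpec("mask", mask=np.asarray(entry["mask"]) > 0.5, **common))
        else:
            rois.append(
                RoiSpec(
                    "circle",
                    center=tuple(entry["center_px"]),
                    radius=float(entry["radius_px"]),
                    **common,
                )
            )
    return rois


def save_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
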