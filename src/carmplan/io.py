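"""File formats: JSON pose streams, annotations, frustum descriptions, run
configuration, and raster depth conversion.

Pose files are JSON documents ``{"poses": [{"timestamp": s, "frame": str,
"matrix": [[...4x4 row-major...]], "units": "mm"}, ...]}``; every matrix is
validated as a rigid transform on load, with the offending record index in
the error message. Annotations are ``{"annotations": [{"frustum_id": str,
"pixel": [x, y], "label": str}, ...]}``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .geometry import RigidTransform
from .frustum import Frustum, Intrinsics, XRayImage
from .reconstruction import Annotation

__all__ = [
    "PoseRecord",
    "RunConfig",
    "read_poses",
    "write_poses",
    "read_annotations",
    "write_annotations",
    "read_frustums",
    "write_frustums",
    "convert_16to8",
    "load_config",
]


@dataclass(frozen=True)
class PoseRecord:
    timestamp: float
    transform: RigidTransform
    frame: str = ""
    units: str = "mm"


def read_poses(path) -> List[PoseRecord]:
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "poses" not in doc:
        raise ValueError(f"{path}: expected a JSON object with a 'poses' list")
    records = []
    for i, rec in enumerate(doc["poses"]):
        try:
            M = np.asarray(rec["matrix"], dtype=float)
            T = RigidTransform.from_matrix(M)
        except (KeyError, ValueError, TypeError) as err:
            raise ValueError(f"{path}: invalid pose record {i}: {err}") from err
        units = rec.get("units", "mm")
        if units != "mm":
            raise ValueError(f"{path}: pose record {i} has units {units!r}; only mm supported")
        records.append(
            PoseRecord(float(rec.get("timestamp", i)), T, rec.get("frame", ""), units)
        )
    return records


def write_poses(path, records: Sequence[PoseRecord]) -> None:
    doc = {
        "poses": [
            {
                "timestamp": r.timestamp,
                "frame": r.frame,
                "units": r.units,
                "matrix": r.transform.as_matrix().tolist(),
            }
            for r in records
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_annotations(path) -> List[Annotation]:
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "annotations" not in doc:
        raise ValueError(f"{path}: expected a JSON object with an 'annotations' list")
    out = []
    for i, rec in enumerate(doc["annotations"]):
        try:
            out.append(Annotation(rec["frustum_id"], rec["pixel"], rec.get("label", "")))
        except (KeyError, ValueError, TypeError) as err:
            raise ValueError(f"{path}: invalid annotation {i}: {err}") from err
    return out


def write_annotations(path, annotations: Sequence[Annotation]) -> None:
    doc = {
        "annotations": [
            {"frustum_id": a.frustum_id, "pixel": a.pixel.tolist(), "label": a.label}
            for a in annotations
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _intrinsics_to_dict(intr: Intrinsics) -> dict:
    return {
        "focal_length_mm": intr.focal_length,
        "pixel_spacing_mm": intr.pixel_spacing,
        "image_size_px": list(intr.image_size),
        "principal_point_px": list(intr.principal_point),
    }


def _intrinsics_from_dict(d: dict) -> Intrinsics:
    return Intrinsics(
        focal_length=d.get("focal_length_mm", 1000.0),
        pixel_spacing=d.get("pixel_spacing_mm", 0.3),
        image_size=tuple(d.get("image_size_px", (1024, 1024))),
        principal_point=tuple(d["principal_point_px"]) if "principal_point_px" in d else None,
    )


def read_frustums(path) -> Dict[str, Frustum]:
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "frustums" not in doc:
        raise ValueError(f"{path}: expected a JSON object with a 'frustums' list")
    out = {}
    for i, rec in enumerate(doc["frustums"]):
        try:
            pose = RigidTransform.from_matrix(np.asarray(rec["source_pose"], dtype=float))
            fr = Frustum(
                source_pose=pose,
                intrinsics=_intrinsics_from_dict(rec.get("intrinsics", {})),
                near=rec.get("near_mm"),
                frustum_id=rec.get("frustum_id", f"view{i}"),
            )
        except (KeyError, ValueError, TypeError) as err:
            raise ValueError(f"{path}: invalid frustum {i}: {err}") from err
        out[fr.frustum_id] = fr
    return out


def write_frustums(path, frustums: Sequence[Frustum]) -> None:
    doc = {
        "frustums": [
            {
                "frustum_id": f.frustum_id,
                "source_pose": f.source_pose.as_matrix().tolist(),
                "near_mm": f.near,
                "intrinsics": _intrinsics_to_dict(f.intrinsics),
            }
            for f in frustums
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def convert_16to8(image: XRayImage) -> XRayImage:
    """Linear min-max rescale of a 16-bit raster to 8 bit, same resolution.

    A constant image has zero dynamic range; it maps to all zeros with a
    warning instead of dividing by zero.
    """
    if image.bit_depth != 16:
        raise ValueError("convert_16to8 expects a 16-bit image")
    px = image.pixels.astype(np.float64)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        warnings.warn("constant image: zero dynamic range, output is all zeros", stacklevel=2)
        out = np.zeros_like(px, dtype=np.uint8)
    else:
        out = np.round((px - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return XRayImage(out, bit_depth=8, spacing=image.spacing)


_CONFIG_KEYS = {"intrinsics", "noise", "seed", "output_dir", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (JSON); unknown keys are rejected."""

    intrinsics: Intrinsics = field(default_factory=Intrinsics)
    rotation_sd_deg: float = 0.0
    translation_sd_mm: float = 0.0
    pixel_sd_px: float = 0.0
    seed: Optional[int] = None
    output_dir: str = "."
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    noise = doc.get("noise", {})
    bad = set(noise) - {"rotation_sd_deg", "translation_sd_mm", "pixel_sd_px"}
    if bad:
        raise ValueError(f"{path}: unknown noise keys {sorted(bad)}")
    return RunConfig(
        intrinsics=_intrinsics_from_dict(doc.get("intrinsics", {})),
        rotation_sd_deg=float(noise.get("rotation_sd_deg", 0.0)),
        translation_sd_mm=float(noise.get("translation_sd_mm", 0.0)),
        pixel_sd_px=float(noise.get("pixel_sd_px", 0.0)),
        seed=doc.get("seed"),
        output_dir=doc.get("output_dir", "."),
        log_level=doc.get("log_level", "INFO"),
    )
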