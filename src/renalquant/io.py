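"""NIfTI + JSON-sidecar image I/O and the versioned contour JSON format.

Image sets are written as NIfTI-1 volumes — either one 4-D file
(``frames.nii.gz``) or one file per frame (``frame_000.nii.gz``, ...) — with
a ``sidecar.json`` that is authoritative for the acquisition schedule
(inversion times, b-values or ASL constants).  Internally arrays use axis
order (slice, row, col); NIfTI files store (x, y, z[, frame]) with the
voxel size on the affine diagonal.

Contours are stored as JSON::

    {"version": 1, "spacing": [dx, dy, dz], "observer_id": "...",
     "slice_count": N,
     "contours": [{"slice": i, "label": "WK", "hole": false,
                   "vertices": [[x, y], ...]}, ...]}

Note the sidecar spacing order is (dx, dy, dz) while the in-memory spacing
tuple is axis-ordered (dz, dy, dx).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import LabelMap
from .qmap import ASLConstants, ASLSet, DWISeries, MOLLISeries, ParameterMap
from .volumetry import Contour, ROISet

__all__ = [
    "write_image_set", "read_image_set", "write_parameter_map",
    "read_parameter_map", "write_contours", "read_contours",
    "write_labelmap", "read_labelmap",
]

CONTOUR_SCHEMA_VERSION = 1


def _affine(spacing) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def _to_nifti_order(vol: np.ndarray) -> np.ndarray:
    # (slice,row,col) == (z,y,x) -> (x,y,z); 4-D gets frames last
    if vol.ndim == 3:
        return np.transpose(vol, (2, 1, 0))
    return np.transpose(vol, (3, 2, 1, 0))


def _from_nifti_order(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        return np.transpose(arr, (2, 1, 0))
    return np.transpose(arr, (3, 2, 1, 0))


def _save(vol: np.ndarray, spacing, path: Path) -> None:
    nib.save(nib.Nifti1Image(_to_nifti_order(vol), _affine(spacing)), str(path))


def _load(path: Path) -> np.ndarray:
    return _from_nifti_order(np.asarray(nib.load(str(path)).get_fdata()))


def write_image_set(obj, out_dir, per_frame: bool = False) -> Path:
    """Write a MOLLI / DWI / ASL image set with its JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, MOLLISeries):
        sidecar = {"kind": "molli", "ti_ms": list(obj.ti_ms),
                   "spacing": list(obj.spacing[::-1])}
        _write_frames(obj.frames, obj.spacing, out_dir, per_frame)
    elif isinstance(obj, DWISeries):
        sidecar = {"kind": "dwi", "b_s_per_mm2": list(obj.b_s_per_mm2),
                   "spacing": list(obj.spacing[::-1])}
        _write_frames(obj.frames, obj.spacing, out_dir, per_frame)
    elif isinstance(obj, ASLSet):
        c = obj.constants
        sidecar = {"kind": "asl", "spacing": list(obj.spacing[::-1]),
                   "constants": {
                       "t_ms": c.t_ms, "tau_ms": c.tau_ms,
                       "delta_t_ms": c.delta_t_ms, "alpha": c.alpha,
                       "lambda_ml_per_g": c.lambda_ml_per_g,
                       "t1_blood_ms": c.t1_blood_ms,
                       "t1_app_ms": c.t1_app_ms}}
        _save(obj.label_img, obj.spacing, out_dir / "label.nii.gz")
        _save(obj.control_img, obj.spacing, out_dir / "control.nii.gz")
        _save(obj.m0_img, obj.spacing, out_dir / "m0.nii.gz")
    else:
        raise TypeError(f"unsupported image set type {type(obj).__name__}")
    (out_dir / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def _write_frames(frames, spacing, out_dir: Path, per_frame: bool) -> None:
    if per_frame:
        for i, frame in enumerate(frames):
            _save(frame, spacing, out_dir / f"frame_{i:03d}.nii.gz")
    else:
        _save(frames, spacing, out_dir / "frames.nii.gz")


def _read_frames(out_dir: Path) -> np.ndarray:
    stacked = out_dir / "frames.nii.gz"
    if stacked.exists():
        return _load(stacked)
    singles = sorted(out_dir.glob("frame_*.nii.gz"))
    if not singles:
        raise FileNotFoundError(f"no frames.nii.gz or frame_*.nii.gz in {out_dir}")
    return np.stack([_load(p) for p in singles])


def read_image_set(path):
    """Read an image set directory back into its typed object.

    The sidecar schedule is validated against the stored frame count; a
    mismatch raises with both counts named.
    """
    path = Path(path)
    sidecar = json.loads((path / "sidecar.json").read_text())
    spacing = tuple(sidecar["spacing"][::-1])
    kind = sidecar["kind"]
    if kind == "molli":
        frames = _read_frames(path)
        if frames.shape[0] != len(sidecar["ti_ms"]):
            raise ValueError(
                f"{frames.shape[0]} frames but {len(sidecar['ti_ms'])} "
                "inversion times in sidecar")
        return MOLLISeries(frames=frames, ti_ms=tuple(sidecar["ti_ms"]),
                           spacing=spacing)
    if kind == "dwi":
        frames = _read_frames(path)
        if frames.shape[0] != len(sidecar["b_s_per_mm2"]):
            raise ValueError(
                f"{frames.shape[0]} frames but {len(sidecar['b_s_per_mm2'])} "
                "b-values in sidecar")
        return DWISeries(frames=frames,
                         b_s_per_mm2=tuple(sidecar["b_s_per_mm2"]),
                         spacing=spacing)
    if kind == "asl":
        return ASLSet(
            label_img=_load(path / "label.nii.gz"),
            control_img=_load(path / "control.nii.gz"),
            m0_img=_load(path / "m0.nii.gz"),
            constants=ASLConstants(**sidecar["constants"]),
            spacing=spacing)
    raise ValueError(f"unknown image-set kind {kind!r}")


def write_parameter_map(pmap: ParameterMap, spacing, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _save(np.nan_to_num(pmap.values, nan=0.0), spacing, out_dir / "map.nii.gz")
    _save(pmap.mask.astype(np.uint8).astype(float), spacing,
          out_dir / "mask.nii.gz")
    meta = {"units": pmap.units, "info": pmap.info,
            "spacing": list(tuple(spacing)[::-1])}
    (out_dir / "sidecar.json").write_text(json.dumps(meta, indent=1))
    return out_dir


def read_parameter_map(path) -> ParameterMap:
    path = Path(path)
    meta = json.loads((path / "sidecar.json").read_text())
    mask = _load(path / "mask.nii.gz") > 0.5
    values = _load(path / "map.nii.gz")
    values = np.where(mask, values, np.nan)
    return ParameterMap(values=values, units=meta["units"], mask=mask,
                        info=meta.get("info", {}))


def write_labelmap(labelmap: LabelMap, path) -> None:
    _save(labelmap.labels.astype(float), labelmap.spacing, Path(path))


def read_labelmap(path, spacing=None) -> LabelMap:
    img = nib.load(str(path))
    labels = _from_nifti_order(np.asarray(img.get_fdata())).round().astype(np.int8)
    if spacing is None:
        dx, dy, dz = np.abs(np.diag(img.affine)[:3])
        spacing = (dz, dy, dx)
    return LabelMap(labels=labels, spacing=spacing)


def write_contours(rois: ROISet, path) -> None:
    doc = {
        "version": CONTOUR_SCHEMA_VERSION,
        "spacing": list(rois.spacing[::-1]),  # (dx, dy, dz)
        "observer_id": rois.observer_id,
        "slice_count": rois.slice_count,
        "contours": [
            {"slice": c.slice_index, "label": c.label, "hole": c.hole,
             "vertices": np.asarray(c.vertices).tolist()}
            for c in rois.contours],
    }
    Path(path).write_text(json.dumps(doc))


def read_contours(path) -> ROISet:
    doc = json.loads(Path(path).read_text())
    if doc.get("version") != CONTOUR_SCHEMA_VERSION:
        raise ValueError(f"unsupported contour schema version {doc.get('version')}")
    contours = [Contour(slice_index=int(c["slice"]),
                        vertices=np.asarray(c["vertices"], dtype=float),
                        label=c["label"], hole=bool(c["hole"]))
                for c in doc["contours"]]
    return ROISet(contours=contours, spacing=tuple(doc["spacing"][::-1]),
                  observer_id=doc.get("observer_id", ""),
                  slice_count=int(doc.get("slice_count", 0)))
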