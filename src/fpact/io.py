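"""File I/O: NIfTI volumes and masks, centerline JSON, TDC CSV, configs.

NIfTI is the canonical volume format. The affine is diagonal in the
voxel spacing (RAS); acquisition metadata that NIfTI cannot carry
(time, kVp, mA) lives in a JSON sidecar next to the image. Perfusion
maps are written float32 with undefined voxels as NaN; masks uint8 {0,1};
territory/capacity label maps uint8 plus a JSON legend.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray

from .acquisition import TimeDensityCurve
from .territories import Centerline, TerritoryLabelMap
from .volume import BinaryMask, GridMismatchError, VolumeScan


def _affine(spacing_mm: Sequence[float]) -> NDArray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: VolumeScan, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(vol.hu.astype(np.float32), _affine(vol.spacing_mm))
    nib.save(img, str(path))
    meta = {"time_s": vol.time_s, "kvp": vol.kvp, "ma": vol.ma, "phase": vol.phase}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_volume(path) -> VolumeScan:
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return VolumeScan(
        hu=np.asarray(img.dataobj, dtype=np.float32),
        spacing_mm=spacing,
        time_s=float(meta.get("time_s", 0.0)),
        kvp=float(meta.get("kvp", 100.0)),
        ma=float(meta.get("ma", 200.0)),
        phase=float(meta.get("phase", 75.0)),
    )


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(mask.spacing_mm)
    )
    nib.save(img, str(path))


def read_mask(path, role: str = "myocardium") -> BinaryMask:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask {path} has values {vals}, expected {{0, 1}}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask(arr.astype(bool), spacing, role=role)


def write_map(values: NDArray, spacing_mm, path) -> None:
    """Write a float map (NaN = undefined) as float32 NIfTI."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(spacing_mm))
    nib.save(img, str(path))


def read_map(path) -> Tuple[NDArray, Tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float32), spacing


def write_labelmap(labelmap: TerritoryLabelMap, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(
        labelmap.labels.astype(np.uint8), _affine(labelmap.spacing_mm)
    )
    nib.save(img, str(path))
    legend = {str(k): v for k, v in labelmap.legend.items()}
    _sidecar(path).write_text(json.dumps(legend, indent=1))


def read_labelmap(path) -> TerritoryLabelMap:
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    legend = {
        int(k): v for k, v in json.loads(_sidecar(path).read_text()).items()
    }
    return TerritoryLabelMap(
        np.asarray(img.dataobj).astype(np.uint8), legend, spacing
    )


def write_class_map(classes: NDArray, legend: Dict[int, str], spacing_mm, path) -> None:
    """Write a uint8 class map (e.g. flow capacity) with its JSON legend."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(classes, dtype=np.uint8), _affine(spacing_mm))
    nib.save(img, str(path))
    _sidecar(path).write_text(json.dumps({str(k): v for k, v in legend.items()}, indent=1))


def write_centerlines(lines: Sequence[Centerline], path) -> None:
    doc = []
    for cl in lines:
        entry = {"label": cl.label, "points_mm": cl.points_mm.tolist()}
        if cl.stenosis_arclength_mm is not None:
            entry["stenosis_arclength_mm"] = cl.stenosis_arclength_mm
        doc.append(entry)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_centerlines(path) -> List[Centerline]:
    doc = json.loads(Path(path).read_text())
    return [
        Centerline(
            label=e["label"],
            points_mm=np.asarray(e["points_mm"], dtype=float),
            stenosis_arclength_mm=e.get("stenosis_arclength_mm"),
        )
        for e in doc
    ]


def write_tdc(tdc: TimeDensityCurve, path) -> None:
    pd.DataFrame({"time_s": tdc.time_s, "hu": tdc.hu}).to_csv(path, index=False)


def read_tdc(path, baseline_hu: float = 0.0) -> TimeDensityCurve:
    df = pd.read_csv(path)
    return TimeDensityCurve(
        df["time_s"].to_numpy(), df["hu"].to_numpy(), baseline_hu=baseline_hu
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(doc: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def check_paired_grids(a, b, name_a: str, name_b: str) -> None:
    """Raise a :class:`GridMismatchError` naming both files."""
    if a.shape != b.shape or not np.allclose(a.spacing_mm, b.spacing_mm):
        raise GridMismatchError(
            f"{name_a} (shape {a.shape}, spacing {a.spacing_mm}) does not match "
            f"{name_b} (shape {b.shape}, spacing {b.spacing_mm})"
        )
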