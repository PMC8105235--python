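"""End-to-end low-dose protocol pipeline.

Ties the stages together for a full rest+stress study: V1/V2 perfusion
for both conditions, voxel-wise CFR, coronary territory assignment
(with optional stenosis sub-partition), flow-capacity classification,
and the protocol dose report. All outputs land in one directory with a
manifest; given identical inputs the summary JSON is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import io as fio
from .capacity import CapacityThresholds, capacity_summary, classify_capacity
from .dosimetry import dose_report, lowdose_protocol_model
from .perfusion import PerfusionResult, compute_cfr, compute_perfusion
from .territories import (
    TerritoryLabelMap,
    assign_territories,
    partition_distal,
    territory_cfr,
    territory_stats,
)

log = logging.getLogger("fpact")


@dataclass
class PipelineConfig:
    """Paths and parameters for one low-dose rest+stress study."""

    rest_v1: str
    rest_v2: str
    stress_v1: str
    stress_v2: str
    myocardium: str
    aorta: str
    centerlines: str
    out_dir: str
    baseline_hu: float = 45.0
    trigger_threshold_hu: float = 140.0
    rest_floor: float = 0.1
    capacity_config: Optional[str] = None
    dose: Optional[dict] = None  # kwargs for lowdose_protocol_model
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**fio.load_yaml(path))

    def validate_paths(self) -> None:
        for name in ("rest_v1", "rest_v2", "stress_v1", "stress_v2",
                     "myocardium", "aorta", "centerlines"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def run_lowdose_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute the full protocol; returns the summary dict it also writes."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)

    stage("read inputs")
    myo = fio.read_mask(cfg.myocardium, role="myocardium")
    aorta = fio.read_mask(cfg.aorta, role="aortic-root")
    vols = {}
    for key in ("rest_v1", "rest_v2", "stress_v1", "stress_v2"):
        vols[key] = fio.read_volume(getattr(cfg, key))
        fio.check_paired_grids(vols[key], myo, key, "myocardium mask")
    lines = fio.read_centerlines(cfg.centerlines)

    stage("perfusion")
    results: Dict[str, PerfusionResult] = {}
    for cond in ("rest", "stress"):
        try:
            results[cond] = compute_perfusion(
                vols[f"{cond}_v1"], vols[f"{cond}_v2"], myo, aorta, cfg.baseline_hu
            )
        except Exception as exc:
            raise RuntimeError(f"[{cond} perfusion] {exc}") from exc
        fio.write_map(
            results[cond].perfusion_map, myo.spacing_mm,
            out / f"perfusion_{cond}.nii.gz",
        )

    stage("cfr")
    cfr_map = compute_cfr(results["stress"], results["rest"], rest_floor=cfg.rest_floor)
    fio.write_map(cfr_map, myo.spacing_mm, out / "cfr.nii.gz")

    stage("territories")
    labelmap = assign_territories(myo, lines)
    for cl in lines:
        if cl.stenosis_arclength_mm is not None:
            labelmap = partition_distal(labelmap, cl, myo)
    fio.write_labelmap(labelmap, out / "territories.nii.gz")

    per_territory = {
        cond: territory_stats(results[cond].perfusion_map, labelmap)
        for cond in ("rest", "stress")
    }
    cfr_regional = territory_cfr(
        results["stress"].perfusion_map, results["rest"].perfusion_map, labelmap
    )

    summary: Dict = {
        "perfusion": {c: results[c].summary() for c in ("rest", "stress")},
        "territories": {
            c: per_territory[c].reset_index().to_dict(orient="records")
            for c in ("rest", "stress")
        },
        "cfr_regional": cfr_regional.reset_index().to_dict(orient="records"),
        "config": {
            "baseline_hu": cfg.baseline_hu,
            "trigger_threshold_hu": cfg.trigger_threshold_hu,
            "rest_floor": cfg.rest_floor,
            "seed": cfg.seed,
        },
    }

    if cfg.capacity_config:
        stage("capacity")
        thr = CapacityThresholds.from_yaml(cfg.capacity_config)
        capmap = classify_capacity(cfr_map, results["stress"].perfusion_map, thr)
        fio.write_class_map(
            capmap.classes, capmap.legend, myo.spacing_mm, out / "capacity.nii.gz"
        )
        summary["capacity"] = (
            capacity_summary(capmap, labelmap).reset_index().to_dict(orient="records")
        )

    stage("dose")
    model = lowdose_protocol_model(**(cfg.dose or {}))
    summary["dose"] = dose_report(model).to_dict()

    manifest = sorted(p.name for p in out.iterdir() if p.name != "summary.json")
    summary["manifest"] = manifest
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def export_map_png(values, path, title: str = "", cmap: str = "viridis") -> None:
    """Static mid-slice PNG of a 3D map (rendering convenience only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(values, dtype=float)
    mid = arr.shape[2] // 2
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(arr[:, :, mid].T, origin="lower", cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
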