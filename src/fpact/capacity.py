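"""Coronary flow-capacity classification.

Flow capacity grades myocardium jointly on CFR and absolute stress
perfusion: a region is only as good as its worst axis, so the class
regions form a lower-left-dominant staircase in the (CFR, stress) plane.
Six classes are used, from "scar" (most severe) to "normal".

The numeric cutoffs are population-derived and are deliberately NOT
hard-coded science: they ship as a mandatory YAML config. The example
config bundled with the package carries placeholder values for phantom
experiments and is clearly labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray

from .territories import TerritoryLabelMap

#: canonical class names, most severe first
CLASS_NAMES = (
    "scar",
    "definite ischemia",
    "moderately reduced",
    "mildly reduced",
    "minimally reduced",
    "normal",
)

#: display colours, most severe first (black -> red)
CLASS_COLORS = ("black", "blue", "green", "yellow", "orange", "red")

UNCLASSIFIED = 255


@dataclass
class CapacityThresholds:
    """Lower (CFR, stress perfusion) bounds per class, severe to normal.

    A point belongs to the best class whose both lower bounds it meets;
    the most severe class has bounds (0, 0) so every non-negative point
    is covered. Bounds must be non-decreasing from severe to normal.
    """

    cfr_min: Tuple[float, ...]
    stress_min: Tuple[float, ...]

    def __post_init__(self) -> None:
        self.cfr_min = tuple(float(v) for v in self.cfr_min)
        self.stress_min = tuple(float(v) for v in self.stress_min)
        k = len(CLASS_NAMES)
        if len(self.cfr_min) != k or len(self.stress_min) != k:
            raise ValueError(f"exactly {k} classes required: {CLASS_NAMES}")
        if self.cfr_min[0] != 0.0 or self.stress_min[0] != 0.0:
            raise ValueError("the most severe class must have lower bounds (0, 0)")
        for seq, name in ((self.cfr_min, "CFR"), (self.stress_min, "stress")):
            if any(b > a for a, b in zip(seq[1:], seq[:-1])):
                raise ValueError(f"{name} bounds must be non-decreasing severe->normal")

    @classmethod
    def from_yaml(cls, path) -> "CapacityThresholds":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "CapacityThresholds":
        classes = doc["classes"]
        by_name = {c["name"]: c for c in classes}
        missing = set(CLASS_NAMES) - set(by_name)
        if missing:
            raise ValueError(f"config missing classes: {sorted(missing)}")
        return cls(
            cfr_min=[by_name[n]["cfr_min"] for n in CLASS_NAMES],
            stress_min=[by_name[n]["stress_min"] for n in CLASS_NAMES],
        )

    def to_dict(self) -> dict:
        return {
            "classes": [
                {"name": n, "cfr_min": c, "stress_min": s, "color": col}
                for n, c, s, col in zip(
                    CLASS_NAMES, self.cfr_min, self.stress_min, CLASS_COLORS
                )
            ]
        }


def example_thresholds() -> CapacityThresholds:
    """The bundled placeholder config (phantom experiments only)."""
    with resources.files("fpact.data").joinpath("capacity_example.yaml").open() as fh:
        return CapacityThresholds.from_dict(yaml.safe_load(fh))


@dataclass
class CapacityMap:
    """Class index per voxel (0 = scar ... 5 = normal, 255 = unclassified)."""

    classes: NDArray[np.unsignedinteger]
    legend: Dict[int, str]
    colors: Dict[int, str]


def classify_capacity(
    cfr: Union[float, NDArray],
    stress: Union[float, NDArray],
    thresholds: CapacityThresholds,
) -> "CapacityMap | str":
    """Assign flow-capacity classes to (CFR, stress perfusion) points.

    Scalar inputs return the class name; array inputs return a
    :class:`CapacityMap`. Undefined inputs (NaN) are left unclassified.
    Severity is monotone: raising either CFR or stress perfusion never
    yields a more severe class.
    """
    scalar = np.isscalar(cfr) and np.isscalar(stress)
    cfr_a = np.atleast_1d(np.asarray(cfr, dtype=float))
    str_a = np.atleast_1d(np.asarray(stress, dtype=float))
    if cfr_a.shape != str_a.shape:
        raise ValueError("CFR and stress arrays must be aligned")

    defined = np.isfinite(cfr_a) & np.isfinite(str_a)
    # bounds are non-decreasing, so the per-class pass tests are nested:
    # the class index is the number of satisfied non-scar levels
    level = np.zeros(cfr_a.shape, dtype=np.int64)
    for f, s in zip(thresholds.cfr_min[1:], thresholds.stress_min[1:]):
        level += (cfr_a >= f) & (str_a >= s)
    out = np.where(defined, level, UNCLASSIFIED).astype(np.uint8)

    if scalar:
        idx = int(out.item())
        return CLASS_NAMES[idx] if idx != UNCLASSIFIED else "unclassified"
    legend = dict(enumerate(CLASS_NAMES))
    colors = dict(enumerate(CLASS_COLORS))
    return CapacityMap(classes=out.reshape(np.shape(cfr)), legend=legend, colors=colors)


def capacity_summary(
    capmap: CapacityMap,
    labelmap: TerritoryLabelMap,
) -> pd.DataFrame:
    """Per-territory myocardial-mass fraction in each capacity class.

    Fractions are over classified voxels and sum to 1 per territory (all
    voxels share one mass, so mass fractions equal voxel fractions).
    """
    if capmap.classes.shape != labelmap.labels.shape:
        raise ValueError("capacity map and territory label map grids differ")
    rows = []
    for lid in sorted(labelmap.legend):
        name = labelmap.legend[lid]
        sel = (labelmap.labels == lid) & (capmap.classes != UNCLASSIFIED)
        total = int(sel.sum())
        row = {"territory": name}
        for ci, cname in capmap.legend.items():
            n = int((capmap.classes[sel] == ci).sum())
            row[cname] = n / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("territory")
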