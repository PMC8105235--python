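"""Coronary territory assignment by minimum-cost paths.

Each myocardial voxel is labelled with the coronary centerline it can
reach at least geodesic cost. Paths run on the 26-connected voxel graph
restricted to the myocardium (plus a thin straight corridor connecting
each centerline voxel to its nearest myocardial voxel, since centerlines
lie epicardially, just outside the mask); edge weights are Euclidean
distances between voxel centres in mm. A territory can be further split
at a stenosis: centerline points proximal/distal to the stenosis
arc-length become two source sets and the vessel's voxels are
re-assigned between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .volume import MYOCARDIAL_DENSITY_G_PER_ML, BinaryMask, check_same_grid

#: canonical vessel ordering used for deterministic tie-breaking
VESSEL_ORDER = ("LAD", "LCx", "RCA")


@dataclass
class Centerline:
    """An ordered coronary centerline polyline in world mm coordinates.

    The first point is the ostial end. ``stenosis_arclength_mm``, if set,
    marks a stenosis as arc length from the ostial end.
    """

    label: str
    points_mm: NDArray[np.floating]
    stenosis_arclength_mm: Optional[float] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_mm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("centerline needs >= 2 points of shape (n, 3)")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive centerline points must be distinct")
        self.points_mm = pts
        if self.stenosis_arclength_mm is not None:
            s = float(self.stenosis_arclength_mm)
            if not (0.0 <= s <= self.total_length_mm):
                raise ValueError(
                    f"stenosis arc-length {s} mm outside [0, {self.total_length_mm:.2f}]"
                )
            self.stenosis_arclength_mm = s

    @property
    def total_length_mm(self) -> float:
        seg = np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)
        return float(seg.sum())

    def resample(self, step_mm: float) -> Tuple[NDArray, NDArray]:
        """Resample to <= ``step_mm`` spacing; returns (points, arclengths)."""
        pts = self.points_mm
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(np.ceil(s[-1] / step_mm)) + 1, 2)
        si = np.linspace(0.0, s[-1], n)
        out = np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])
        return out, si


@dataclass
class TerritoryLabelMap:
    """Integer vessel label per voxel; 0 = outside the myocardium."""

    labels: NDArray[np.integer]
    legend: Dict[int, str]
    spacing_mm: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {missing} missing from legend")
        if len(set(self.legend.values())) != len(self.legend):
            raise ValueError("legend must be bijective")

    def mask_for(self, name: str) -> NDArray[np.bool_]:
        ids = [k for k, v in self.legend.items() if v == name]
        if not ids:
            raise KeyError(f"territory {name!r} not in legend")
        return self.labels == ids[0]

    @property
    def names(self) -> List[str]:
        return [self.legend[k] for k in sorted(self.legend)]


def _order_key(label: str) -> Tuple[int, str]:
    base = label.split("-")[0]
    try:
        return (VESSEL_ORDER.index(base), label)
    except ValueError:
        return (len(VESSEL_ORDER), label)


def rasterize_centerline(
    points_mm: NDArray,
    shape: Tuple[int, int, int],
    spacing_mm: Tuple[float, float, float],
) -> NDArray[np.intp]:
    """Map polyline points (resampled at <= half-voxel steps) to voxel indices."""
    step = 0.5 * min(spacing_mm)
    cl = Centerline("tmp", points_mm)
    pts, _ = cl.resample(step)
    idx = np.floor(pts / np.asarray(spacing_mm)).astype(np.intp)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    return np.unique(idx, axis=0)


def _line_voxels(p0: NDArray, p1: NDArray, spacing: NDArray, shape) -> NDArray[np.intp]:
    """Voxels along the straight segment p0->p1 (mm), sampled at half-voxel steps."""
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / (0.5 * float(spacing.min())))) + 1, 2)
    pts = p0[None, :] + np.linspace(0.0, 1.0, n)[:, None] * (p1 - p0)[None, :]
    idx = np.floor(pts / spacing).astype(np.intp)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    return np.unique(idx, axis=0)


_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.intp,
)


def _geodesic_distances(
    domain: NDArray[np.bool_],
    spacing_mm: Tuple[float, float, float],
    source_sets: Sequence[NDArray[np.intp]],
) -> NDArray[np.floating]:
    """Multi-source Dijkstra distances on the 26-connected voxel graph.

    Returns an array (n_source_sets, nx, ny, nz) of geodesic distances in
    mm, inf where unreachable or outside the domain.
    """
    shape = domain.shape
    node_id = -np.ones(shape, dtype=np.int64)
    coords = np.argwhere(domain)
    n = coords.shape[0]
    node_id[tuple(coords.T)] = np.arange(n)
    spacing = np.asarray(spacing_mm, dtype=float)

    rows: List[NDArray] = []
    cols: List[NDArray] = []
    wts: List[NDArray] = []
    for off in _OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
        nb_ok = nb[ok]
        src = node_id[tuple(coords[ok].T)]
        dst = node_id[tuple(nb_ok.T)]
        valid = dst >= 0
        rows.append(src[valid])
        cols.append(dst[valid])
        w = float(np.linalg.norm(off * spacing))
        wts.append(np.full(valid.sum(), w))
    graph = coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    out = np.full((len(source_sets),) + shape, np.inf)
    for k, srcs in enumerate(source_sets):
        ids = node_id[tuple(np.asarray(srcs).T)]
        ids = ids[ids >= 0]
        if ids.size == 0:
            continue
        d = dijkstra(graph, directed=False, indices=ids, min_only=True)
        out[k][tuple(coords.T)] = d
    return out


def assign_territories(
    myo: BinaryMask,
    centerlines: Sequence[Centerline],
    max_gap_mm: float = 10.0,
) -> TerritoryLabelMap:
    """Label each myocardial voxel with its minimum-cost centerline.

    Ties break in the fixed order LAD < LCx < RCA. A centerline whose
    every point lies farther than ``max_gap_mm`` from the myocardium is
    rejected; myocardial voxels unreachable along the restricted domain
    are assigned to the nearest tree by straight-line distance, with a
    warning.
    """
    if len(centerlines) == 0:
        raise ValueError("need at least one centerline")
    if myo.n_voxels == 0:
        raise ValueError("myocardium mask is empty")
    shape, spacing = myo.shape, np.asarray(myo.spacing_mm)
    lines = sorted(centerlines, key=lambda c: _order_key(c.label))

    # distance from any voxel to the myocardium, and nearest-myo voxel indices
    dist_mm, nearest = ndimage.distance_transform_edt(
        ~myo.data, sampling=myo.spacing_mm, return_indices=True
    )

    myo_centers = (np.argwhere(myo.data) + 0.5) * spacing
    myo_tree = cKDTree(myo_centers)

    domain = myo.data.copy()
    source_sets: List[NDArray[np.intp]] = []
    for cl in lines:
        pts, _ = cl.resample(0.5 * float(spacing.min()))
        gap = float(myo_tree.query(pts)[0].min())
        if gap > max_gap_mm:
            raise ValueError(
                f"centerline {cl.label!r} lies > {max_gap_mm} mm from the myocardium "
                f"(closest point {gap:.1f} mm)"
            )
        vox = rasterize_centerline(cl.points_mm, shape, myo.spacing_mm)
        # corridor: straight link from each off-mask source voxel to its
        # nearest myocardial voxel, so sources connect to the tissue graph
        extra = [vox]
        for v in vox[~myo.data[tuple(vox.T)]]:
            tgt = np.array([nearest[k][tuple(v)] for k in range(3)], dtype=np.intp)
            p0 = (v + 0.5) * spacing
            p1 = (tgt + 0.5) * spacing
            extra.append(_line_voxels(p0, p1, spacing, shape))
        vox_all = np.unique(np.concatenate(extra), axis=0)
        domain[tuple(vox_all.T)] = True
        source_sets.append(vox)  # corridors widen the domain, not the source set

    dists = _geodesic_distances(domain, myo.spacing_mm, source_sets)

    labels = np.zeros(shape, dtype=np.uint8)
    m = myo.data
    dm = dists[:, m]  # (K, n_myo)
    best = np.argmin(dm, axis=0)  # first minimum wins: canonical tie order
    unreachable = ~np.isfinite(dm.min(axis=0))
    if unreachable.any():
        warnings.warn(
            f"{int(unreachable.sum())} myocardial voxels unreachable by restricted "
            "paths; assigned by straight-line distance",
            stacklevel=2,
        )
        myo_pts = (np.argwhere(m)[unreachable] + 0.5) * spacing
        euc = np.empty((len(lines), myo_pts.shape[0]))
        for k, cl in enumerate(lines):
            pts, _ = cl.resample(0.5 * float(spacing.min()))
            euc[k] = cKDTree(pts).query(myo_pts)[0]
        best[unreachable] = np.argmin(euc, axis=0)
    labels[m] = best.astype(np.uint8) + 1
    legend = {k + 1: cl.label for k, cl in enumerate(lines)}
    return TerritoryLabelMap(labels=labels, legend=legend, spacing_mm=myo.spacing_mm)


def partition_distal(
    labelmap: TerritoryLabelMap,
    line: Centerline,
    myo: BinaryMask,
) -> TerritoryLabelMap:
    """Split one vessel's territory at its stenosis into proximal/distal parts.

    Centerline source points at arc length <= the stenosis marker form the
    proximal set, the rest the distal set; voxels previously labelled to
    the vessel are re-assigned by minimum-cost path to the nearer set.
    Other territories are untouched. Ties go proximal.
    """
    if line.stenosis_arclength_mm is None:
        raise ValueError(f"centerline {line.label!r} has no stenosis marker")
    vessel_ids = [k for k, v in labelmap.legend.items() if v == line.label]
    if not vessel_ids:
        raise KeyError(f"vessel {line.label!r} not present in the label map legend")
    vid = vessel_ids[0]

    step = 0.5 * min(myo.spacing_mm)
    pts, arcs = line.resample(step)
    s = line.stenosis_arclength_mm
    if s <= 0.0 or s >= line.total_length_mm:
        raise ValueError(
            f"stenosis marker at {s:.2f} mm of {line.total_length_mm:.2f} mm is a "
            "degenerate partition (must lie strictly inside the centerline)"
        )
    prox_pts, dist_pts = pts[arcs <= s], pts[arcs > s]
    if len(prox_pts) == 0 or len(dist_pts) == 0:
        raise ValueError(
            f"stenosis at {s:.2f} mm leaves an empty proximal or distal source set "
            "(degenerate partition)"
        )

    shape, spacing = myo.shape, np.asarray(myo.spacing_mm)
    vessel_mask = labelmap.labels == vid

    dist_mm, nearest = ndimage.distance_transform_edt(
        ~vessel_mask, sampling=myo.spacing_mm, return_indices=True
    )
    domain = vessel_mask.copy()
    source_sets = []
    for sub in (prox_pts, dist_pts):
        vox = rasterize_centerline(sub, shape, myo.spacing_mm)
        extra = [vox]
        for v in vox[~vessel_mask[tuple(vox.T)]]:
            tgt = np.array([nearest[k][tuple(v)] for k in range(3)], dtype=np.intp)
            extra.append(
                _line_voxels((v + 0.5) * spacing, (tgt + 0.5) * spacing, spacing, shape)
            )
        vox_all = np.unique(np.concatenate(extra), axis=0)
        domain[tuple(vox_all.T)] = True
        source_sets.append(vox)

    dists = _geodesic_distances(domain, myo.spacing_mm, source_sets)

    new_labels = labelmap.labels.copy()
    new_id = int(max(labelmap.legend)) + 1
    in_vessel = vessel_mask
    distal = dists[1] < dists[0]  # strict: ties stay proximal
    new_labels[in_vessel & distal] = new_id
    legend = dict(labelmap.legend)
    legend[vid] = f"{line.label}-proximal"
    legend[new_id] = f"{line.label}-distal"
    return TerritoryLabelMap(new_labels, legend, labelmap.spacing_mm)


def territory_stats(
    values: NDArray[np.floating],
    labelmap: TerritoryLabelMap,
) -> pd.DataFrame:
    """Per-territory mean, SD, defined-voxel count, and tissue mass.

    NaN values (undefined voxels) are excluded from mean/SD; mass counts
    every voxel of the territory. Empty territories yield NaN stats with a
    warning.
    """
    if values.shape != labelmap.labels.shape:
        raise ValueError(
            f"value map shape {values.shape} != label map shape {labelmap.labels.shape}"
        )
    vox_ml = float(np.prod(labelmap.spacing_mm)) * 1e-3
    rows = []
    for lid in sorted(labelmap.legend):
        name = labelmap.legend[lid]
        sel = labelmap.labels == lid
        vals = values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"territory {name!r} has no defined voxels", stacklevel=2)
            mean = sd = np.nan
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "territory": name,
                "mean": mean,
                "sd": sd,
                "n_voxels": int(vals.size),
                "mass_g": MYOCARDIAL_DENSITY_G_PER_ML * int(sel.sum()) * vox_ml,
            }
        )
    return pd.DataFrame(rows).set_index("territory")


def territory_cfr(
    stress_map: NDArray[np.floating],
    rest_map: NDArray[np.floating],
    labelmap: TerritoryLabelMap,
) -> pd.DataFrame:
    """Regional CFR as the ratio of paired territory means (stress / rest).

    Averaging order matters: the regional CFR is the ratio of the two
    regional mean perfusions, not the mean of the voxel-wise ratio map.
    """
    s = territory_stats(stress_map, labelmap)
    r = territory_stats(rest_map, labelmap)
    out = pd.DataFrame(
        {
            "stress_mean": s["mean"],
            "rest_mean": r["mean"],
            "cfr": s["mean"] / r["mean"],
        }
    )
    return out
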