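"""Two-volume first-pass perfusion quantification.

The single-compartment, inflow-only model states that before venous
outflow the average myocardial perfusion is

    P_AVE = (dM_C/dt) / (C_in * M_T)

where dM_C/dt is the rate of contrast accumulation in the myocardium,
C_in the arterial input amplitude (aortic-root enhancement averaged
between the two volumes) and M_T the myocardial tissue mass. Because
iodine concentration and HU enhancement are proportional through the
same constant in numerator and denominator, everything is computed in
HU. The per-voxel perfusion redistributes P_AVE by the local enhancement
change:

    P = P_AVE * dHU / dHU_AVE = dHU / (dt_min * C_in * rho)

with rho = 1.055 g/mL the myocardial tissue density and dt in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from numpy.typing import NDArray

from .volume import (
    MYOCARDIAL_DENSITY_G_PER_ML,
    BinaryMask,
    VolumeScan,
    check_same_grid,
)


class NoEnhancementError(RuntimeError):
    """Contrast never arrived (C_in <= 0 or mean myocardial dHU <= 0)."""


def mip_combine(volumes: Sequence[VolumeScan]) -> VolumeScan:
    """Voxel-wise maximum intensity projection across co-registered volumes.

    Metadata (time, tube settings) is inherited from the first volume.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    first = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        check_same_grid(first, v, names=["volumes[0]", f"volumes[{i}]"])
    hu = first.hu
    for v in volumes[1:]:
        hu = np.maximum(hu, v.hu)
    return VolumeScan(
        hu=hu,
        spacing_mm=first.spacing_mm,
        time_s=first.time_s,
        kvp=first.kvp,
        ma=first.ma,
        phase=first.phase,
    )


def compute_cin(
    v1: VolumeScan,
    v2: VolumeScan,
    aorta: BinaryMask,
    baseline_hu: float,
    subtract_baseline: bool = True,
) -> float:
    """Arterial input amplitude: aortic-ROI mean HU averaged between V1 and V2.

    By default the baseline blood-pool HU is subtracted so C_in is the
    contrast-attributable enhancement; ``subtract_baseline=False`` returns
    the raw averaged HU instead.
    """
    check_same_grid(v1, v2, aorta, names=["V1", "V2", "aorta"])
    if aorta.n_voxels == 0:
        raise ValueError("aortic ROI mask is empty")
    roi = aorta.data
    mean1 = float(v1.hu[roi].mean())
    mean2 = float(v2.hu[roi].mean())
    cin = (mean1 + mean2) / 2.0
    if subtract_baseline:
        cin -= baseline_hu
    if cin <= 0:
        raise NoEnhancementError(
            f"C_in = {cin:.2f} HU <= 0: no contrast arrival in the aortic ROI"
        )
    return cin


def compute_tissue_mass(myo: BinaryMask) -> float:
    """Myocardial tissue mass M_T (g) = rho * voxel count * voxel volume (mL)."""
    n = myo.n_voxels
    if n == 0:
        raise ValueError("myocardium mask is empty")
    return MYOCARDIAL_DENSITY_G_PER_ML * n * myo.voxel_volume_ml


@dataclass
class PerfusionResult:
    """Average and per-voxel perfusion with all model constituents.

    ``perfusion_map`` is mL/min/g on the myocardium mask and NaN outside;
    raw (possibly negative) voxel values are retained. ``P_AVE`` equals
    the mask mean of the map by construction.
    """

    p_ave: float
    perfusion_map: NDArray[np.floating]
    mask: BinaryMask
    cin_hu: float
    tissue_mass_g: float
    dhu_ave: float
    dhu_map: NDArray[np.floating]
    dt_s: float
    dmc_dt: float  # HU*mL/min, summed-enhancement rate proxy
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def shape(self):
        return self.perfusion_map.shape

    def summary(self) -> dict:
        return {
            "P_AVE_ml_min_g": self.p_ave,
            "C_in_hu": self.cin_hu,
            "M_T_g": self.tissue_mass_g,
            "dHU_AVE": self.dhu_ave,
            "dt_s": self.dt_s,
            "dMc_dt_hu_ml_min": self.dmc_dt,
            "n_voxels": self.mask.n_voxels,
        }


def compute_perfusion(
    v1: VolumeScan,
    v2: VolumeScan,
    myo: BinaryMask,
    aorta: BinaryMask,
    baseline_hu: float,
    subtract_baseline: bool = True,
) -> PerfusionResult:
    """First-pass perfusion from two volumes.

    Raises
    ------
    ValueError
        If V2 does not follow V1 in time or a mask is empty.
    NoEnhancementError
        If C_in <= 0 or the mask-mean enhancement change is <= 0.
    """
    check_same_grid(v1, v2, myo, aorta, names=["V1", "V2", "myocardium", "aorta"])
    dt_s = v2.time_s - v1.time_s
    if dt_s <= 0:
        raise ValueError(f"V2 time ({v2.time_s} s) must exceed V1 time ({v1.time_s} s)")
    cin = compute_cin(v1, v2, aorta, baseline_hu, subtract_baseline=subtract_baseline)
    mt = compute_tissue_mass(myo)

    m = myo.data
    dhu = np.full(v1.shape, np.nan, dtype=np.float64)
    dhu[m] = v2.hu[m].astype(np.float64) - v1.hu[m].astype(np.float64)
    dhu_ave = float(dhu[m].mean())
    if dhu_ave <= 0:
        raise NoEnhancementError(
            f"mean myocardial enhancement change {dhu_ave:.3f} HU <= 0: "
            "no net myocardial enhancement"
        )

    dt_min = dt_s / 60.0
    rho = MYOCARDIAL_DENSITY_G_PER_ML
    # dM_C/dt proxy: summed voxel enhancement change * voxel volume / time
    dmc_dt = dhu_ave * myo.n_voxels * myo.voxel_volume_ml / dt_min
    # P_AVE = dM_C/dt / (C_in * M_T), algebraically dHU_AVE / (dt * C_in * rho)
    p_ave = dmc_dt / (cin * mt)
    pmap = dhu / (dt_min * cin * rho)

    return PerfusionResult(
        p_ave=p_ave,
        perfusion_map=pmap,
        mask=myo,
        cin_hu=cin,
        tissue_mass_g=mt,
        dhu_ave=dhu_ave,
        dhu_map=dhu,
        dt_s=float(dt_s),
        dmc_dt=dmc_dt,
        spacing_mm=v1.spacing_mm,
    )


DEFAULT_REST_FLOOR = 0.1  # mL/min/g below which voxel CFR is undefined


def compute_cfr(
    stress: PerfusionResult,
    rest: PerfusionResult,
    rest_floor: float = DEFAULT_REST_FLOOR,
) -> NDArray[np.floating]:
    """Voxel-wise coronary flow reserve, stress / rest.

    Voxels whose rest perfusion falls below ``rest_floor`` are flagged
    undefined (NaN) rather than producing unstable ratios; regional CFR
    should come from paired regional means (see
    :func:`fpact.territories.territory_cfr`), not from averaging this map.
    """
    check_same_grid(stress.mask, rest.mask, names=["stress mask", "rest mask"])
    if not np.array_equal(stress.mask.data, rest.mask.data):
        raise ValueError("stress and rest masks must be identical")
    cfr = np.full(stress.shape, np.nan, dtype=np.float64)
    m = stress.mask.data
    p_rest = rest.perfusion_map
    ok = m & (p_rest >= rest_floor)
    cfr[ok] = stress.perfusion_map[ok] / p_rest[ok]
    return cfr


def bin_voxels(
    values: NDArray[np.floating], factor: int
) -> NDArray[np.floating]:
    """Block-mean downsampling of a map over ``factor``^3 neighbourhoods.

    Undefined voxels (NaN, i.e. outside the mask) are excluded from each
    block mean; blocks containing no defined voxel stay NaN. ``factor=1``
    is the identity.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("binning factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return np.array(values, dtype=np.float64, copy=True)
    arr = np.asarray(values, dtype=np.float64)
    pad = [(0, (-s) % factor) for s in arr.shape]
    arr = np.pad(arr, pad, constant_values=np.nan)
    nx, ny, nz = (s // factor for s in arr.shape)
    blocks = arr.reshape(nx, factor, ny, factor, nz, factor)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(blocks, axis=(1, 3, 5))
    return out
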