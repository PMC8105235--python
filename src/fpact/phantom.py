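"""Synthetic dynamic cardiac CT phantom with known ground truth.

The phantom emulates a contrast-enhanced swine acquisition: a half-
ellipsoid LV myocardial shell, an aortic-root cylinder carrying a
first-pass bolus, three epicardial coronary centerlines, per-territory
rest/stress perfusion, and tube-current-dependent Gaussian HU noise.

Tissue follows the inflow-only single-compartment model: before venous
outflow, each myocardial voxel accumulates contrast at a rate set by its
local perfusion, so its enhancement is

    HU(t) = HU_tissue + P_true * rho * integral_0^t C_a(tau) dtau

with C_a the arterial enhancement above the blood baseline (HU), the
integral in HU*min and rho = 1.055 g/mL. With a gamma-variate arterial
input the integral has an exact closed form through the regularised
lower incomplete gamma function, which is what the simulator uses.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.typing import NDArray
from scipy import special

from .acquisition import TimeDensityCurve
from .territories import Centerline, TerritoryLabelMap, assign_territories, partition_distal
from .volume import (
    MYOCARDIAL_DENSITY_G_PER_ML,
    BinaryMask,
    VolumeScan,
    voxel_center_grids,
)


def gamma_variate(
    t, amplitude: float, alpha: float, beta: float, t0: float
):
    """Gamma-variate bolus enhancement (HU above baseline) at time ``t`` (s).

    ``amplitude * ((t - t0) / (alpha * beta))**alpha * exp(alpha - (t - t0)/beta)``
    for ``t > t0``, zero before arrival. The peak equals ``amplitude``
    exactly at ``t = t0 + alpha * beta``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("gamma-variate shape and scale must be > 0")
    if amplitude <= 0:
        raise ValueError("gamma-variate amplitude must be > 0")
    t = np.asarray(t, dtype=float)
    tp = t - t0
    out = np.zeros_like(tp)
    pos = tp > 0
    out[pos] = amplitude * (tp[pos] / (alpha * beta)) ** alpha * np.exp(
        alpha - tp[pos] / beta
    )
    return out if out.ndim else float(out)


@dataclass
class GammaVariateAIF:
    """First-pass arterial input: gamma-variate enhancement above baseline."""

    amplitude_hu: float = 170.0
    alpha: float = 1.5
    beta_s: float = 10.0
    t0_s: float = 1.5

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta_s <= 0 or self.amplitude_hu <= 0:
            raise ValueError("AIF amplitude, shape and scale must all be > 0")

    @property
    def peak_time_s(self) -> float:
        return self.t0_s + self.alpha * self.beta_s

    @property
    def outflow_window_s(self) -> float:
        """End of the assumed outflow-free window (twice the time to peak)."""
        return self.t0_s + 2.0 * self.alpha * self.beta_s

    def value(self, t) -> NDArray:
        return gamma_variate(t, self.amplitude_hu, self.alpha, self.beta_s, self.t0_s)

    def cumulative(self, t) -> NDArray:
        """Exact integral of :meth:`value` from 0 to ``t``, in HU*s."""
        t = np.asarray(t, dtype=float)
        tp = np.maximum(t - self.t0_s, 0.0)
        a, b = self.alpha, self.beta_s
        scale = (
            self.amplitude_hu
            * np.exp(a)
            * (a * b) ** (-a)
            * b ** (a + 1)
            * special.gamma(a + 1)
        )
        out = scale * special.gammainc(a + 1, tp / b)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "type": "gamma",
            "amplitude_hu": self.amplitude_hu,
            "alpha": self.alpha,
            "beta_s": self.beta_s,
            "t0_s": self.t0_s,
        }


@dataclass
class LinearRampAIF:
    """Linear arterial enhancement ramp (exercises the exactness limit).

    Enhancement is ``slope * (t - t0)`` for ``t > t0`` (optionally capped
    at ``plateau_hu``). With a linear input the two-point C_in equals the
    window-mean input exactly, so two-volume recovery is exact.
    """

    slope_hu_per_s: float = 25.0
    t0_s: float = 1.0
    plateau_hu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope_hu_per_s <= 0:
            raise ValueError("ramp slope must be > 0")

    @property
    def outflow_window_s(self) -> float:
        return np.inf

    def value(self, t) -> NDArray:
        t = np.asarray(t, dtype=float)
        out = np.maximum(t - self.t0_s, 0.0) * self.slope_hu_per_s
        if self.plateau_hu is not None:
            out = np.minimum(out, self.plateau_hu)
        return out if out.ndim else float(out)

    def cumulative(self, t) -> NDArray:
        t = np.asarray(t, dtype=float)
        tp = np.maximum(t - self.t0_s, 0.0)
        if self.plateau_hu is None:
            out = 0.5 * self.slope_hu_per_s * tp**2
        else:
            t_sat = self.plateau_hu / self.slope_hu_per_s
            ramp = 0.5 * self.slope_hu_per_s * np.minimum(tp, t_sat) ** 2
            out = ramp + self.plateau_hu * np.maximum(tp - t_sat, 0.0)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "type": "linear",
            "slope_hu_per_s": self.slope_hu_per_s,
            "t0_s": self.t0_s,
            "plateau_hu": self.plateau_hu,
        }


def aif_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type", "gamma")
    if kind == "gamma":
        return GammaVariateAIF(**d)
    if kind == "linear":
        return LinearRampAIF(**{k: v for k, v in d.items() if v is not None})
    raise ValueError(f"unknown AIF type {kind!r}")


#: Per-territory rest/stress flows (mL/min/g), swine defaults
DEFAULT_TERRITORY_FLOWS: Dict[str, Dict[str, float]] = {
    "LAD": {"rest": 0.58, "stress": 2.07},
    "LCx": {"rest": 0.53, "stress": 2.15},
    "RCA": {"rest": 0.37, "stress": 1.79},
}

#: Flows distal to a sub-occlusive LAD stenosis
DEFAULT_LAD_DISTAL_FLOWS: Dict[str, float] = {"rest": 0.58, "stress": 1.20}


@dataclass
class PhantomSpec:
    """Full description of the digital cardiac phantom.

    Geometry is in world mm; masks are generated on the voxel grid with
    voxel centres at ``(index + 0.5) * spacing``. The LV myocardium is the
    half-ellipsoid shell between the outer and inner semi-axes below the
    base plane ``z = center_mm[2]``; the aortic root is a cylinder above
    the base, disjoint from the shell.
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    spacing_mm: Tuple[float, float, float] = (0.43, 0.43, 0.5)
    center_mm: Tuple[float, float, float] = (20.64, 20.64, 36.0)
    outer_semiaxes_mm: Tuple[float, float, float] = (17.0, 17.0, 34.0)
    inner_semiaxes_mm: Tuple[float, float, float] = (11.0, 11.0, 28.0)
    aorta_center_mm: Tuple[float, float, float] = (20.64, 20.64, 42.0)
    aorta_radius_mm: float = 5.0
    aorta_height_mm: float = 8.0
    baseline_tissue_hu: float = 50.0
    baseline_blood_hu: float = 45.0
    background_hu: float = 0.0
    aif: "GammaVariateAIF | LinearRampAIF" = field(default_factory=GammaVariateAIF)
    territory_flows: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TERRITORY_FLOWS.items()}
    )
    lad_distal_flows: Optional[Dict[str, float]] = None
    lad_stenosis_arclength_mm: Optional[float] = None
    noise_sigma_ref_hu: float = 25.0
    noise_ref_ma: float = 50.0
    noise_ma_exponent: float = 0.5
    baseline_drift_hu: float = 0.0
    frame_times_s: Tuple[float, ...] = tuple(np.round(np.arange(26) * 0.72, 5))
    frame_ma: "float | Tuple[float, ...]" = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not all(
            i < o for i, o in zip(self.inner_semiaxes_mm, self.outer_semiaxes_mm)
        ):
            raise ValueError("inner shell must lie strictly inside the outer shell")
        times = np.asarray(self.frame_times_s, dtype=float)
        if times.size < 1 or (times.size > 1 and not np.all(np.diff(times) > 0)):
            raise ValueError("frame times must be strictly increasing")
        for name, flows in self.territory_flows.items():
            for cond, val in flows.items():
                if val < 0:
                    raise ValueError(f"{name} {cond} perfusion must be >= 0")
        if (self.lad_distal_flows is None) != (self.lad_stenosis_arclength_mm is None):
            raise ValueError(
                "lad_distal_flows and lad_stenosis_arclength_mm must be set together"
            )
        if self.noise_sigma_ref_hu < 0 or self.noise_ref_ma <= 0:
            raise ValueError("noise parameters must be non-negative (sigma) / positive (mA)")

    def noise_sigma(self, ma: float) -> float:
        """Gaussian HU noise sigma at tube current ``ma`` (quantum scaling)."""
        return self.noise_sigma_ref_hu * (self.noise_ref_ma / ma) ** self.noise_ma_exponent

    def frame_currents(self) -> NDArray:
        times = np.asarray(self.frame_times_s)
        if np.isscalar(self.frame_ma):
            return np.full(times.size, float(self.frame_ma))
        ma = np.asarray(self.frame_ma, dtype=float)
        if ma.size != times.size:
            raise ValueError("frame_ma length must match frame_times_s")
        return ma

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aif"] = self.aif.to_dict()
        d["frame_times_s"] = list(self.frame_times_s)
        if not np.isscalar(d["frame_ma"]):
            d["frame_ma"] = list(d["frame_ma"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "aif" in d and isinstance(d["aif"], dict):
            d["aif"] = aif_from_dict(d["aif"])
        for key in ("grid_shape", "spacing_mm", "center_mm", "outer_semiaxes_mm",
                    "inner_semiaxes_mm", "aorta_center_mm", "frame_times_s"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("frame_ma"), list):
            d["frame_ma"] = tuple(d["frame_ma"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the phantom knows: masks, centerlines, truth maps, TDC."""

    myo: BinaryMask
    aorta: BinaryMask
    cavity: NDArray[np.bool_]
    centerlines: List[Centerline]
    labelmap: TerritoryLabelMap
    perfusion_rest: NDArray[np.floating]
    perfusion_stress: NDArray[np.floating]
    tdc_noiseless: Optional[TimeDensityCurve]

    def perfusion(self, condition: str) -> NDArray[np.floating]:
        if condition not in ("rest", "stress"):
            raise ValueError("condition must be 'rest' or 'stress'")
        return self.perfusion_rest if condition == "rest" else self.perfusion_stress


def _shell_centerlines(spec: PhantomSpec) -> List[Centerline]:
    """Three epicardial polylines on the outer shell surface, base to apex."""
    cx, cy, zb = spec.center_mm
    a, b, c = spec.outer_semiaxes_mm
    thetas = np.deg2rad(np.linspace(85.0, 10.0, 40))  # base rim -> near apex
    azimuths = {"LAD": 90.0, "LCx": 210.0, "RCA": 330.0}
    lines = []
    for label, phi_deg in azimuths.items():
        phi = np.deg2rad(phi_deg)
        pts = np.column_stack(
            [
                cx + a * np.sin(thetas) * np.cos(phi),
                cy + b * np.sin(thetas) * np.sin(phi),
                zb - c * np.cos(thetas),
            ]
        )
        sten = (
            spec.lad_stenosis_arclength_mm
            if (label == "LAD" and spec.lad_stenosis_arclength_mm is not None)
            else None
        )
        lines.append(Centerline(label, pts, stenosis_arclength_mm=sten))
    return lines


def build_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Masks, centerlines, territory labels and true perfusion maps."""
    X, Y, Z = voxel_center_grids(spec.grid_shape, spec.spacing_mm)
    cx, cy, zb = spec.center_mm

    def in_half_ellipsoid(semi):
        ax, ay, az = semi
        q = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - zb) / az) ** 2
        return (q <= 1.0) & (Z <= zb)

    outer = in_half_ellipsoid(spec.outer_semiaxes_mm)
    inner = in_half_ellipsoid(spec.inner_semiaxes_mm)
    myo_arr = outer & ~inner
    if not myo_arr.any():
        raise ValueError("phantom geometry produced an empty myocardium")

    ax_, ay_, az_ = spec.aorta_center_mm
    aorta_arr = (
        ((X - ax_) ** 2 + (Y - ay_) ** 2 <= spec.aorta_radius_mm**2)
        & (np.abs(Z - az_) <= spec.aorta_height_mm / 2.0)
    )
    if not aorta_arr.any():
        raise ValueError("phantom geometry produced an empty aortic ROI")
    if (aorta_arr & myo_arr).any():
        raise ValueError("aortic cylinder overlaps the myocardial shell")

    myo = BinaryMask(myo_arr, spec.spacing_mm, role="myocardium")
    aorta = BinaryMask(aorta_arr, spec.spacing_mm, role="aortic-root")

    centerlines = _shell_centerlines(spec)
    labelmap = assign_territories(myo, centerlines)
    if spec.lad_stenosis_arclength_mm is not None:
        lad = next(c for c in centerlines if c.label == "LAD")
        labelmap = partition_distal(labelmap, lad, myo)

    flows = {k: dict(v) for k, v in spec.territory_flows.items()}
    if spec.lad_distal_flows is not None:
        flows["LAD-proximal"] = flows.pop("LAD")
        flows["LAD-distal"] = dict(spec.lad_distal_flows)

    maps = {}
    for cond in ("rest", "stress"):
        pmap = np.full(spec.grid_shape, np.nan)
        for lid, name in labelmap.legend.items():
            if name not in flows:
                raise ValueError(f"no {cond} flow configured for territory {name!r}")
            pmap[labelmap.labels == lid] = flows[name][cond]
        maps[cond] = pmap

    times = np.asarray(spec.frame_times_s, dtype=float)
    if times.size >= 3:
        tdc = TimeDensityCurve(
            times,
            spec.baseline_blood_hu + np.asarray(spec.aif.value(times)),
            baseline_hu=spec.baseline_blood_hu,
        )
    else:
        tdc = None  # a 2-frame pair has no meaningful monitoring curve

    return GroundTruth(
        myo=myo,
        aorta=aorta,
        cavity=inner,
        centerlines=centerlines,
        labelmap=labelmap,
        perfusion_rest=maps["rest"],
        perfusion_stress=maps["stress"],
        tdc_noiseless=tdc,
    )


def simulate_acquisition(
    spec: PhantomSpec,
    condition: str = "rest",
    truth: Optional[GroundTruth] = None,
) -> Tuple[List[VolumeScan], GroundTruth]:
    """Simulate a dynamic contrast-enhanced series for one flow condition.

    Identical ``spec`` (including ``seed``) reproduces bit-identical
    volumes. Pass a precomputed ``truth`` to reuse the (deterministic)
    geometry across repeated noise realisations.
    """
    if truth is None:
        truth = build_ground_truth(spec)
    p_true = truth.perfusion(condition)

    times = np.asarray(spec.frame_times_s, dtype=float)
    currents = spec.frame_currents()
    if times[-1] > spec.aif.outflow_window_s:
        warnings.warn(
            f"frame times extend to {times[-1]:.1f} s, beyond the outflow-free "
            f"window ({spec.aif.outflow_window_s:.1f} s); the inflow-only tissue "
            "model may not hold there",
            stacklevel=2,
        )

    myo = truth.myo.data
    blood = truth.aorta.data | truth.cavity
    p_myo = np.nan_to_num(p_true, nan=0.0)[myo]
    rho = MYOCARDIAL_DENSITY_G_PER_ML

    rng = np.random.default_rng(spec.seed)
    volumes: List[VolumeScan] = []
    for t, ma in zip(times, currents):
        hu = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
        hu[blood] = spec.baseline_blood_hu + float(spec.aif.value(t))
        integral_hu_min = float(spec.aif.cumulative(t)) / 60.0
        hu[myo] = spec.baseline_tissue_hu + p_myo * rho * integral_hu_min
        hu += spec.baseline_drift_hu
        sigma = spec.noise_sigma(ma)
        if sigma > 0:
            hu += rng.normal(0.0, sigma, size=spec.grid_shape)
        volumes.append(
            VolumeScan(
                hu=hu.astype(np.float32),
                spacing_mm=spec.spacing_mm,
                time_s=float(t),
                kvp=100.0,
                ma=float(ma),
            )
        )
    return volumes, truth


def default_swine_spec(
    with_stenosis: bool = False, seed: int = 0
) -> PhantomSpec:
    """The default swine-like phantom.

    The gamma-variate bolus gives a trigger-to-peak delay of 5.76 s on the
    default frame grid (the in-vivo range was 4.10-8.93 s, mean 5.69 s)
    and the per-territory rest/stress flows are the measured swine means.
    With ``with_stenosis=True`` a mid-LAD stenosis splits the LAD
    territory, with distal stress flow 1.20 mL/min/g.
    """
    kwargs = dict(seed=seed)
    if with_stenosis:
        lad_len = _shell_centerlines(PhantomSpec(seed=seed))[0].total_length_mm
        kwargs.update(
            lad_distal_flows=dict(DEFAULT_LAD_DISTAL_FLOWS),
            lad_stenosis_arclength_mm=0.5 * lad_len,
        )
    return PhantomSpec(**kwargs)
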