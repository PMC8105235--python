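"""Bolus-tracking trigger logic and systematic V1/V2 selection.

The two perfusion volumes are chosen from the aortic time-density curve
(TDC): V1 is the first volume after aortic enhancement exceeds the
trigger threshold (default 140 HU above the baseline blood pool), and V2
is the volume at the aortic enhancement peak. The delay between them,
ΔT, is what a prospective low-dose acquisition re-uses.

Triggering is sample-and-hold: the first discrete sample at or above the
threshold triggers, with no interpolation between samples — this is how a
scanner's monitoring scan behaves and keeps every oracle exact. An
optional whole-frame latency models the hardware delay between the
monitoring frame that crosses the threshold and the first full volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from numpy.typing import NDArray

from .volume import BinaryMask, VolumeScan, check_same_grid


class TriggerNotReachedError(RuntimeError):
    """The aortic TDC never exceeded baseline + threshold."""


class DegenerateBolusError(RuntimeError):
    """The TDC peak does not occur strictly after the trigger."""


@dataclass
class TimeDensityCurve:
    """Aortic enhancement versus time.

    Parameters
    ----------
    time_s : array
        Sample times in seconds, strictly ascending, at least 3 samples.
    hu : array
        Aortic blood-pool HU at each sample.
    baseline_hu : float
        Measured baseline blood-pool HU (pre-contrast monitoring frame).
    """

    time_s: NDArray[np.floating]
    hu: NDArray[np.floating]
    baseline_hu: float = 0.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.hu = np.asarray(self.hu, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size < 3:
            raise ValueError("TDC needs >= 3 samples")
        if self.hu.shape != self.time_s.shape:
            raise ValueError("time and HU arrays must have equal length")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("sample times must be strictly ascending")
        if not (np.all(np.isfinite(self.time_s)) and np.all(np.isfinite(self.hu))):
            raise ValueError("TDC contains non-finite values")

    @property
    def enhancement(self) -> NDArray[np.floating]:
        """HU above the baseline blood pool."""
        return self.hu - self.baseline_hu


@dataclass
class TriggerConfig:
    """Bolus-tracking trigger: threshold in HU above baseline (default 140)."""

    threshold_hu: float = 140.0
    latency_frames: int = 0

    def __post_init__(self) -> None:
        if self.threshold_hu <= 0:
            raise ValueError("trigger threshold must be > 0 HU")
        if self.latency_frames < 0:
            raise ValueError("latency must be >= 0 frames")


def _trigger_index(tdc: TimeDensityCurve, cfg: TriggerConfig) -> int:
    above = tdc.hu >= tdc.baseline_hu + cfg.threshold_hu
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise TriggerNotReachedError(
            f"trigger not reached: max enhancement {tdc.enhancement.max():.1f} HU "
            f"< threshold {cfg.threshold_hu:.1f} HU"
        )
    i = int(idx[0]) + cfg.latency_frames
    if i >= tdc.time_s.size:
        raise TriggerNotReachedError("trigger latency extends past the acquisition")
    return i


def detect_trigger(tdc: TimeDensityCurve, cfg: TriggerConfig) -> float:
    """Time (s) of the first sample at or above baseline + threshold."""
    return float(tdc.time_s[_trigger_index(tdc, cfg)])


def _peak_index(tdc: TimeDensityCurve) -> int:
    # argmax returns the first occurrence: ties break to the earliest sample
    return int(np.argmax(tdc.hu))


def find_peak(tdc: TimeDensityCurve) -> float:
    """Time (s) of the global TDC maximum; ties break to the earliest sample."""
    return float(tdc.time_s[_peak_index(tdc)])


def estimate_delta_t(tdc: TimeDensityCurve, cfg: TriggerConfig) -> float:
    """ΔT (s) between the trigger crossing and the aortic enhancement peak."""
    t_trig = detect_trigger(tdc, cfg)
    t_peak = find_peak(tdc)
    dt = t_peak - t_trig
    if dt <= 0:
        raise DegenerateBolusError(
            f"peak ({t_peak:.2f} s) at or before trigger ({t_trig:.2f} s)"
        )
    return float(dt)


class V1V2Selection(NamedTuple):
    """Result of systematic V1/V2 selection from a dynamic series."""

    i1: int
    i2: int
    v1: VolumeScan
    v2: VolumeScan
    tdc: "TimeDensityCurve | None"


def series_tdc(
    series: Sequence[VolumeScan], aorta: BinaryMask, baseline_hu: float
) -> TimeDensityCurve:
    """Aortic-ROI-mean TDC of a dynamic series."""
    if aorta.n_voxels == 0:
        raise ValueError("aortic ROI mask is empty")
    for i, vol in enumerate(series):
        check_same_grid(vol, aorta, names=[f"series[{i}]", "aorta"])
    times = np.array([v.time_s for v in series], dtype=float)
    means = np.array([float(v.hu[aorta.data].mean()) for v in series])
    return TimeDensityCurve(times, means, baseline_hu=baseline_hu)


def select_v1_v2(
    series: Sequence[VolumeScan],
    aorta: BinaryMask,
    baseline_hu: float,
    cfg: TriggerConfig | None = None,
) -> V1V2Selection:
    """Select (V1, V2) from a dynamic series by trigger + peak on the ROI TDC.

    V1 is the first volume at/after the trigger crossing; V2 the volume at
    the TDC peak (earliest on ties). A monotonically rising TDC puts V2 at
    the last frame and emits a warning that the true peak may lie beyond
    the acquisition.
    """
    if cfg is None:
        cfg = TriggerConfig()
    if len(series) < 2:
        raise ValueError("need at least two volumes to select V1/V2")
    if len(series) == 2:
        # already-triggered low-dose pair: identity pass-through
        v1, v2 = series
        if v2.time_s <= v1.time_s:
            raise ValueError("two-frame series must be in ascending time order")
        return V1V2Selection(i1=0, i2=1, v1=v1, v2=v2, tdc=None)
    tdc = series_tdc(series, aorta, baseline_hu)
    i1 = _trigger_index(tdc, cfg)
    i2 = _peak_index(tdc)
    if i2 == len(series) - 1 and np.all(np.diff(tdc.hu) > 0):
        warnings.warn(
            "aortic enhancement rises through the last frame: "
            "peak may lie beyond the acquisition",
            stacklevel=2,
        )
    if i2 <= i1:
        raise DegenerateBolusError(
            f"TDC peak (frame {i2}) not after trigger (frame {i1})"
        )
    return V1V2Selection(i1=i1, i2=i2, v1=series[i1], v2=series[i2], tdc=tdc)
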