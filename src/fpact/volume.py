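"""Core in-memory containers for CT volumes and masks.

All grids are 3D numpy arrays indexed (x, y, z), 0-based. World
coordinates are millimetres; the centre of voxel ``(i, j, k)`` lies at
``((i + 0.5) * dx, (j + 0.5) * dy, (k + 0.5) * dz)``. Paired volumes and
masks must share shape and spacing exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from numpy.typing import NDArray

#: Density of myocardial tissue, grams per millilitre.
MYOCARDIAL_DENSITY_G_PER_ML = 1.055


class GridMismatchError(ValueError):
    """Two grids that must be co-registered differ in shape or spacing."""


@dataclass
class VolumeScan:
    """A single CT volume in Hounsfield units with acquisition metadata.

    Parameters
    ----------
    hu : ndarray
        3D array of HU values, axis order (x, y, z).
    spacing_mm : tuple of float
        Voxel edge lengths in mm per axis.
    time_s : float
        Acquisition time of the volume in seconds (series clock).
    kvp : float
        Tube voltage in kVp.
    ma : float
        Tube current in mA.
    phase : float
        Cardiac phase tag as % of the R-R interval.
    """

    hu: NDArray[np.floating]
    spacing_mm: Tuple[float, float, float]
    time_s: float = 0.0
    kvp: float = 100.0
    ma: float = 200.0
    phase: float = 75.0

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.hu.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.hu.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("volume contains non-finite HU values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.hu.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mm^3 = 1e-3 mL)."""
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz * 1.0e-3


@dataclass
class BinaryMask:
    """A boolean mask aligned to a :class:`VolumeScan` grid.

    ``role`` tags the anatomical meaning ("myocardium" or "aortic-root").
    """

    data: NDArray[np.bool_]
    spacing_mm: Tuple[float, float, float]
    role: str = "myocardium"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != np.bool_:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask values must be in {{0, 1}}, found {vals}")
            arr = arr.astype(bool)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        self.data = arr
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz * 1.0e-3


def check_same_grid(*objs, names: Optional[Sequence[str]] = None) -> None:
    """Raise :class:`GridMismatchError` unless all objects share shape and spacing."""
    if len(objs) < 2:
        return
    if names is None:
        names = [f"object{i}" for i in range(len(objs))]
    ref = objs[0]
    for obj, name in zip(objs[1:], list(names)[1:]):
        if obj.shape != ref.shape or not np.allclose(obj.spacing_mm, ref.spacing_mm):
            raise GridMismatchError(
                f"grid mismatch between {names[0]} (shape {ref.shape}, spacing "
                f"{ref.spacing_mm}) and {name} (shape {obj.shape}, spacing {obj.spacing_mm})"
            )


def voxel_center_grids(
    shape: Tuple[int, int, int], spacing_mm: Tuple[float, float, float]
) -> Tuple[NDArray, NDArray, NDArray]:
    """World-coordinate (mm) grids of voxel centres, axis order (x, y, z)."""
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing_mm)]
    return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]
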