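"""Protocol radiation dosimetry: CTDIvol, SSDE, DLP and effective dose.

Per-volume CTDIvol (32-cm phantom reference) scales linearly with tube
current at fixed kVp. SSDE corrects CTDIvol for patient size through the
AAPM TG-204 conversion factor, an exponential in effective diameter fit
against the 32-cm reference phantom. Effective dose is DLP times an
anatomic conversion coefficient (0.014 mSv/mGy/cm for chest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

# AAPM TG-204 exponential fit, 32-cm phantom: f = a * exp(-b * D)
TG204_A_32CM = 3.704369
TG204_B_32CM = 0.03671937
TG204_DIAMETER_RANGE_CM = (6.0, 55.0)

DEFAULT_CHEST_K = 0.014  # mSv per mGy*cm


@dataclass
class VolumeExposure:
    """One or more identical volume scans within a protocol component."""

    name: str
    kvp: float
    ma: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.ma <= 0 or self.kvp <= 0 or self.count < 1:
            raise ValueError("kVp, mA must be > 0 and count >= 1")


@dataclass
class ScanDoseModel:
    """Dose model anchored to one reference per-volume CTDIvol measurement."""

    ref_ctdi_mgy: float
    ref_ma: float
    ref_kvp: float
    volumes: List[VolumeExposure] = field(default_factory=list)
    scan_length_cm: float = 16.0
    effective_diameter_cm: float = 23.0
    k_msv_per_mgy_cm: float = DEFAULT_CHEST_K
    monitoring_ctdi_mgy: float = 0.0  # bolus-tracking slab, excluded by default

    def __post_init__(self) -> None:
        if min(self.ref_ctdi_mgy, self.ref_ma, self.ref_kvp, self.scan_length_cm,
               self.effective_diameter_cm, self.k_msv_per_mgy_cm) <= 0:
            raise ValueError("doses, currents, lengths and coefficients must be > 0")
        for v in self.volumes:
            if v.kvp != self.ref_kvp:
                raise ValueError(
                    f"volume {v.name!r} at {v.kvp} kVp: kVp scaling is unsupported "
                    f"(reference is {self.ref_kvp} kVp)"
                )


def ctdi_per_volume(model: ScanDoseModel, ma: float, kvp: Optional[float] = None) -> float:
    """CTDIvol (mGy) of a single volume at tube current ``ma``, linear scaling."""
    if ma <= 0:
        raise ValueError("tube current must be > 0")
    if kvp is not None and kvp != model.ref_kvp:
        raise ValueError(
            f"kVp {kvp} differs from reference {model.ref_kvp}: scaling unsupported"
        )
    return model.ref_ctdi_mgy * ma / model.ref_ma


def protocol_ctdi(model: ScanDoseModel) -> Dict[str, float]:
    """Per-component and total CTDIvol32 (mGy) of the modelled protocol."""
    per: Dict[str, float] = {}
    for v in model.volumes:
        dose = ctdi_per_volume(model, v.ma, v.kvp) * v.count
        per[v.name] = per.get(v.name, 0.0) + dose
    per["total"] = sum(d for n, d in per.items() if n != "total")
    return per


def ssde_factor(effective_diameter_cm: float) -> float:
    """TG-204 32-cm-phantom size conversion factor; monotone decreasing in D."""
    lo, hi = TG204_DIAMETER_RANGE_CM
    if not (lo <= effective_diameter_cm <= hi):
        raise ValueError(
            f"effective diameter {effective_diameter_cm} cm outside the "
            f"published fit range [{lo}, {hi}] cm"
        )
    return TG204_A_32CM * float(np.exp(-TG204_B_32CM * effective_diameter_cm))


def effective_dose(
    ctdi_mgy: float, length_cm: float, k: float = DEFAULT_CHEST_K
) -> Tuple[float, float]:
    """(DLP in mGy*cm, effective dose in mSv) from CTDIvol and scan length."""
    if ctdi_mgy < 0 or length_cm <= 0 or k <= 0:
        raise ValueError("CTDI must be >= 0; length and k must be > 0")
    dlp = ctdi_mgy * length_cm
    return dlp, dlp * k


@dataclass
class DoseReport:
    """Full dose summary of a protocol."""

    components_ctdi_mgy: Dict[str, float]
    total_ctdi_mgy: float
    ssde_conversion: float
    components_ssde_mgy: Dict[str, float]
    total_ssde_mgy: float
    dlp_mgy_cm: float
    effective_dose_msv: float
    size_specific_effective_dose_msv: float
    notes: List[str]

    def to_dict(self) -> dict:
        return {
            "components_ctdi_mgy": self.components_ctdi_mgy,
            "total_ctdi_mgy": self.total_ctdi_mgy,
            "ssde_conversion": self.ssde_conversion,
            "components_ssde_mgy": self.components_ssde_mgy,
            "total_ssde_mgy": self.total_ssde_mgy,
            "dlp_mgy_cm": self.dlp_mgy_cm,
            "effective_dose_msv": self.effective_dose_msv,
            "size_specific_effective_dose_msv": self.size_specific_effective_dose_msv,
            "notes": self.notes,
        }


def dose_report(model: ScanDoseModel) -> DoseReport:
    """Compute CTDIvol, SSDE, DLP and effective doses for a protocol model.

    SSDE is computed from the effective diameter; one shared factor scales
    every component. The bolus-tracking monitoring dose is reported in the
    notes if nonzero but excluded from totals.
    """
    per = protocol_ctdi(model)
    total = per.pop("total")
    f = ssde_factor(model.effective_diameter_cm)
    per_ssde = {k_: v * f for k_, v in per.items()}
    dlp, ed = effective_dose(total, model.scan_length_cm, model.k_msv_per_mgy_cm)
    _, ed_size = effective_dose(total * f, model.scan_length_cm, model.k_msv_per_mgy_cm)
    notes = [
        f"SSDE factor {f:.4f} computed from effective diameter "
        f"{model.effective_diameter_cm:.1f} cm (TG-204, 32 cm phantom)"
    ]
    if model.monitoring_ctdi_mgy > 0:
        notes.append(
            f"bolus-tracking monitoring dose {model.monitoring_ctdi_mgy} mGy "
            "excluded from totals"
        )
    return DoseReport(
        components_ctdi_mgy=per,
        total_ctdi_mgy=total,
        ssde_conversion=f,
        components_ssde_mgy=per_ssde,
        total_ssde_mgy=total * f,
        dlp_mgy_cm=dlp,
        effective_dose_msv=ed,
        size_specific_effective_dose_msv=ed_size,
        notes=notes,
    )


def lowdose_protocol_model(
    ref_ctdi_mgy: float = 4.6,
    ref_ma: float = 200.0,
    ref_kvp: float = 100.0,
    **kwargs,
) -> ScanDoseModel:
    """The four-volume low-dose protocol.

    Rest: V1 at 50 mA plus V2 at 200 mA (the CTA volume); stress: V1 and
    V2 both at 50 mA.
    """
    vols = [
        VolumeExposure("rest+CTA", ref_kvp, 50.0),
        VolumeExposure("rest+CTA", ref_kvp, 200.0),
        VolumeExposure("stress", ref_kvp, 50.0, count=2),
    ]
    return ScanDoseModel(ref_ctdi_mgy, ref_ma, ref_kvp, volumes=vols, **kwargs)


def reference_protocol_model(
    ref_ctdi_mgy: float = 4.6,
    ref_ma: float = 200.0,
    ref_kvp: float = 100.0,
    volumes_per_condition: int = 20,
    **kwargs,
) -> ScanDoseModel:
    """The dynamic reference protocol: 2 x 20 volumes at full tube current."""
    vols = [
        VolumeExposure("rest", ref_kvp, ref_ma, count=volumes_per_condition),
        VolumeExposure("stress", ref_kvp, ref_ma, count=volumes_per_condition),
    ]
    return ScanDoseModel(ref_ctdi_mgy, ref_ma, ref_kvp, volumes=vols, **kwargs)
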