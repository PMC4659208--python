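"""Pressure boundary conditions from vital signs and perfusion targets.

The inlet pressure of the network is the cerebral perfusion pressure

    CPP = MAP - ICP,
    MAP ~= DP + 0.01 * exp(4.14 - 40.74/HR) * (SP - DP),

with diastolic/systolic pressures DP/SP (mmHg) and heart rate HR
(beats/min).  Outlet pressures at the efferent territories (ACA, MCA,
PCA) are configured constants representing the distal beds; the lumped
cerebrovascular resistance of each territory follows from CBF = CPP/CVR
at the territory's share of total cerebral blood flow.

Defaults reproduce the standard resting parameterization: DP 80, SP 120,
HR 80 giving MAP 95 mmHg (rounded), ICP 3 mmHg so CPP 92 mmHg, total CBF
12.5 ml/s split 22/45/33 % over ACA/MCA/PCA, and outlet pressures
46 / 56 / 43.5 mmHg.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .units import S_PER_MIN

__all__ = [
    "VitalSigns",
    "PerfusionConstants",
    "BoundarySet",
    "mean_arterial_pressure",
    "cerebral_perfusion_pressure",
    "lumped_cvr",
    "build_boundary_set",
]

#: Default outlet pressures (mmHg) per efferent territory.
DEFAULT_OUTLET_PRESSURES = {"ACA": 46.0, "MCA": 56.0, "PCA": 43.5}


@dataclass(frozen=True)
class VitalSigns:
    """Systemic vitals entering the MAP estimate (mmHg, beats/min)."""

    diastolic_pressure: float = 80.0
    systolic_pressure: float = 120.0
    heart_rate: float = 80.0

    def __post_init__(self) -> None:
        if not self.diastolic_pressure > 0:
            raise ValueError("diastolic pressure must be positive")
        if self.systolic_pressure < self.diastolic_pressure:
            raise ValueError(
                f"systolic ({self.systolic_pressure}) must be >= diastolic "
                f"({self.diastolic_pressure})")
        if not self.heart_rate > 0:
            raise ValueError("heart rate must be positive")


@dataclass(frozen=True)
class PerfusionConstants:
    """Intracranial pressure, total CBF and its territorial split.

    ``fraction_aca`` + ``fraction_mca`` + ``fraction_pca`` must sum to 1;
    each territory comprises both sides (e.g. the ACA share feeds the two
    A2 outlets together).
    """

    intracranial_pressure: float = 3.0
    total_cbf: float = 12.5            # ml/s
    fraction_aca: float = 0.22
    fraction_mca: float = 0.45
    fraction_pca: float = 0.33

    def __post_init__(self) -> None:
        if self.intracranial_pressure < 0:
            raise ValueError("ICP must be >= 0")
        if not self.total_cbf > 0:
            raise ValueError("total CBF must be positive")
        s = self.fraction_aca + self.fraction_mca + self.fraction_pca
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"territory fractions must sum to 1, got {s}")
        if min(self.fraction_aca, self.fraction_mca, self.fraction_pca) <= 0:
            raise ValueError("territory fractions must be positive")


@dataclass(frozen=True)
class BoundarySet:
    """Inlet and outlet pressures with the CVRs they derive from.

    Pressures in mmHg, CVRs in mmHg/(ml/min).  ``inlet_pressure`` is the
    CPP applied at every afferent root; each efferent class carries one
    outlet pressure.
    """

    inlet_pressure: float
    outlet_pressure_aca: float
    outlet_pressure_mca: float
    outlet_pressure_pca: float
    cvr_aca: float
    cvr_mca: float
    cvr_pca: float

    def __post_init__(self) -> None:
        for name in ("aca", "mca", "pca"):
            out = getattr(self, f"outlet_pressure_{name}")
            if out <= 0:
                raise ValueError(f"outlet pressure {name.upper()} must be positive")
            if out >= self.inlet_pressure:
                raise ValueError(
                    f"outlet pressure {name.upper()} ({out} mmHg) must be below "
                    f"the inlet pressure ({self.inlet_pressure} mmHg)")

    def outlet_pressure(self, klass: str) -> float:
        """Outlet pressure for an efferent class name ('ACA'|'MCA'|'PCA')."""
        return getattr(self, f"outlet_pressure_{klass.lower()}")


def mean_arterial_pressure(vitals: VitalSigns) -> float:
    """Estimated MAP (mmHg) from DP, SP and heart rate.

    Uses the heart-rate–dependent weighting of the pulse pressure,
    MAP = DP + 0.01*exp(4.14 - 40.74/HR)*(SP - DP); at rest the weight is
    close to the familiar one-third.  Full precision is returned; round
    for reporting.
    """
    w = 0.01 * math.exp(4.14 - 40.74 / vitals.heart_rate)
    return vitals.diastolic_pressure + w * (
        vitals.systolic_pressure - vitals.diastolic_pressure)


def cerebral_perfusion_pressure(map_value: float, icp: float) -> float:
    """CPP = MAP - ICP (mmHg); rejects the non-physiological MAP <= ICP."""
    if icp < 0:
        raise ValueError("ICP must be >= 0")
    if map_value <= icp:
        raise ValueError(
            f"MAP ({map_value} mmHg) must exceed ICP ({icp} mmHg)")
    return map_value - icp


def lumped_cvr(cpp: float, regional_flow_ml_min: float) -> float:
    """Territory cerebrovascular resistance CVR = CPP / CBF.

    ``regional_flow_ml_min`` is the territory flow in ml/min; the result
    is in mmHg/(ml/min).
    """
    if regional_flow_ml_min <= 0:
        raise ValueError("regional flow must be positive")
    return cpp / regional_flow_ml_min


def build_boundary_set(vitals: VitalSigns = VitalSigns(),
                       constants: PerfusionConstants = PerfusionConstants(),
                       outlet_pressures: dict[str, float] | None = None,
                       ) -> BoundarySet:
    """Assemble the full boundary-condition set.

    The inlet pressure is the CPP from the MAP chain (kept at full
    precision).  Outlet pressures are configured constants — defaulting
    to 46 / 56 / 43.5 mmHg for ACA / MCA / PCA — rather than being
    re-derived from the CVRs, whose printed-derivation step is ambiguous;
    the CVR fields record the CPP/flow quotients for reporting.
    """
    cpp = cerebral_perfusion_pressure(
        mean_arterial_pressure(vitals), constants.intracranial_pressure)
    outs = dict(DEFAULT_OUTLET_PRESSURES)
    if outlet_pressures:
        unknown = set(outlet_pressures) - set(outs)
        if unknown:
            raise ValueError(f"unknown efferent classes: {sorted(unknown)}")
        outs.update(outlet_pressures)
    cbf_ml_min = constants.total_cbf * S_PER_MIN
    return BoundarySet(
        inlet_pressure=cpp,
        outlet_pressure_aca=outs["ACA"],
        outlet_pressure_mca=outs["MCA"],
        outlet_pressure_pca=outs["PCA"],
        cvr_aca=lumped_cvr(cpp, constants.fraction_aca * cbf_ml_min),
        cvr_mca=lumped_cvr(cpp, constants.fraction_mca * cbf_ml_min),
        cvr_pca=lumped_cvr(cpp, constants.fraction_pca * cbf_ml_min),
    )


def derivation_table(vitals: VitalSigns = VitalSigns(),
                     constants: PerfusionConstants = PerfusionConstants(),
                     ) -> dict[str, float]:
    """The full boundary-condition derivation chain as a flat mapping.

    Values are reported at the conventional precision (MAP and CPP to the
    nearest integer mmHg, CVRs to two decimals); used by the CLI ``bc``
    command and the examples.
    """
    map_full = mean_arterial_pressure(vitals)
    cpp_full = cerebral_perfusion_pressure(
        map_full, constants.intracranial_pressure)
    bset = build_boundary_set(vitals, constants)
    return {
        "MAP_mmHg": round(map_full),
        "CPP_mmHg": round(cpp_full),
        "CVR_ACA_mmHg_per_ml_min": round(bset.cvr_aca, 2),
        "CVR_MCA_mmHg_per_ml_min": round(bset.cvr_mca, 2),
        "CVR_PCA_mmHg_per_ml_min": round(bset.cvr_pca, 2),
        "inlet_pressure_mmHg": bset.inlet_pressure,
        "outlet_ACA_mmHg": bset.outlet_pressure_aca,
        "outlet_MCA_mmHg": bset.outlet_pressure_mca,
        "outlet_PCA_mmHg": bset.outlet_pressure_pca,
    }
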