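"""Mechanical circulatory support device models.

Both pumps use the minimal rotodynamic characteristic

    c_speed * omega^2 - c_flow * q^2 - r * q = delta_p

solved for the non-negative flow ``q`` against the pressure head ``delta_p``
imposed by the circulation.  The Impella CP is a transvalvular axial pump
(LV -> ascending aorta) with ten performance levels P0-P9; VA-ECMO is a
centrifugal pump draining the venous reservoir and returning to the left
iliac artery.  Neither pump is allowed to run backwards; at zero speed the
branch is inert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from . import _kernel

#: Impella CP performance-level speed table (rpm).
PLEVEL_RPM: Dict[str, int] = {
    "P0": 0, "P1": 23000, "P2": 31000, "P3": 33000, "P4": 35000,
    "P5": 37000, "P6": 39000, "P7": 42000, "P8": 44000, "P9": 46000,
}


def plevel_to_rpm(level: str) -> int:
    """Exact table lookup of the P-level speed; unknown levels raise KeyError."""
    try:
        return PLEVEL_RPM[level]
    except KeyError:
        raise KeyError(f"unknown Impella performance level: {level!r}") from None


@dataclass
class ImpellaParameters:
    c_speed: float            # mmHg/rpm^2
    c_flow: float             # mmHg*s^2/ml^2
    r_cannula: float          # mmHg*s/ml
    q_max_mean: float = 3.7   # L/min, published mean-flow capability cap
    level_rpm_map: Dict[str, int] = field(default_factory=lambda: dict(PLEVEL_RPM))

    def __post_init__(self):
        if min(self.c_speed, self.c_flow, self.r_cannula) <= 0:
            raise ValueError("Impella coefficients must be > 0")
        if self.level_rpm_map != PLEVEL_RPM:
            raise ValueError("level_rpm_map must be the exact P0-P9 speed table")


@dataclass
class EcmoParameters:
    c_speed: float   # mmHg/rpm^2
    c_flow: float    # mmHg*s^2/ml^2
    r_circuit: float  # mmHg*s/ml, drainage cannula + oxygenator + return

    def __post_init__(self):
        if min(self.c_speed, self.c_flow, self.r_circuit) <= 0:
            raise ValueError("ECMO coefficients must be > 0")


def impella_flow(p_lv: float, p_ao: float, level: str,
                 ip: ImpellaParameters) -> float:
    """Instantaneous Impella flow (ml/s) against the head p_ao - p_lv."""
    rpm = plevel_to_rpm(level)
    if rpm == 0:
        return 0.0
    head_avail = ip.c_speed * rpm * rpm - (p_ao - p_lv)
    return float(_kernel.pump_flow_root(head_avail, ip.c_flow, ip.r_cannula))


def ecmo_flow(p_ven: float, p_iliac: float, rpm: float,
              ep: EcmoParameters) -> float:
    """Instantaneous ECMO circuit flow (ml/s) against the head p_iliac - p_ven."""
    if rpm < 0:
        raise ValueError("rpm must be >= 0")
    if rpm == 0:
        return 0.0
    head_avail = ep.c_speed * rpm * rpm - (p_iliac - p_ven)
    return float(_kernel.pump_flow_root(head_avail, ep.c_flow, ep.r_circuit))


def suction_guard(p_lv: float, q_impella: float, threshold: float = 2.0,
                  floor: float = -5.0) -> float:
    """Linearly derate Impella flow as LV pressure falls toward collapse.

    Identity above ``threshold``; zero at or below ``floor``; linear ramp in
    between.  Mimics the flow loss seen clinically when the inlet cage sucks
    against an under-filled ventricle.
    """
    return q_impella * float(_kernel.suction_factor(p_lv, threshold, floor))
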