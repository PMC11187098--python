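"""Time-varying elastance ventricle and valve elements.

The pneumatically driven silicone ventricle of the bench loop is represented
by the standard 0D equivalent, ``P_lv = E(t) * (V_lv - V0)``, with a periodic
double-Hill activation between the diastolic elastance ``e_min`` and the
end-systolic elastance ``e_max``.  Cardiogenic shock is a reduction of
``e_max`` (loss of contractility) with the vascular side unchanged apart from
the circulating volume that sets the filling pressure.

Valves are competent one-way resistances with a C1-smooth diode transition
(exactly zero flow against the gradient; no regurgitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernel


@dataclass
class ElastanceParameters:
    e_max: float            # mmHg/ml, end-systolic elastance
    e_min: float            # mmHg/ml, diastolic elastance
    v0: float               # ml, volume-axis intercept
    t_sys_frac: float = 0.3  # systolic fraction of the cycle
    hr: float = 75.0        # beats/min (fixed-rate drive)

    def __post_init__(self):
        if not (self.e_max > self.e_min > 0):
            raise ValueError("need e_max > e_min > 0")
        if not (0 < self.t_sys_frac < 1):
            raise ValueError("t_sys_frac must lie in (0, 1)")
        if self.hr <= 0:
            raise ValueError("hr must be > 0")

    @property
    def period(self) -> float:
        return 60.0 / self.hr


@lru_cache(maxsize=64)
def _peak(t_sys_frac: float) -> float:
    return _kernel.activation_peak(t_sys_frac)


def elastance_at(t, p: ElastanceParameters):
    """E(t) in mmHg/ml; periodic with the cycle, range [e_min, e_max]."""
    tau = np.mod(np.asarray(t, dtype=float), p.period) / p.period
    a1 = 0.5 * p.t_sys_frac
    a2 = p.t_sys_frac
    x1 = (tau / a1) ** _kernel.HILL_N1
    x2 = (tau / a2) ** _kernel.HILL_N2
    act = (x1 / (1.0 + x1)) / (1.0 + x2) / _peak(p.t_sys_frac)
    e = p.e_min + (p.e_max - p.e_min) * act
    return float(e) if np.isscalar(t) else e


def lv_pressure(v_lv: float, t: float, p: ElastanceParameters) -> float:
    """Ventricular pressure: linear in volume at fixed time, zero at v0."""
    if v_lv < 0:
        raise ValueError("v_lv must be >= 0")
    return elastance_at(t, p) * (v_lv - p.v0)


@dataclass
class ValveParameters:
    r_open: float           # mmHg*s/ml forward resistance when open
    smoothing: float = 0.5  # mmHg, half-width of the soft diode transition

    def __post_init__(self):
        if self.r_open <= 0:
            raise ValueError("r_open must be > 0")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")


def valve_flow(p_up: float, p_down: float, vp: ValveParameters) -> float:
    """One-way valve flow in ml/s (>= 0; exactly 0 for adverse gradients)."""
    return float(_kernel.diode_flow(p_up - p_down, vp.r_open, vp.smoothing))
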