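"""Hydraulic network data model of the mock circulatory loop.

The loop is the electrical analog of a pneumatically driven ventricle ejecting
into a silicone aortic arch (nonlinear stiffness-law compliance) with a
brachiocephalic branch, a descending segment to the iliac artery, a systemic
resistance, and an open venous reservoir (linear compliance) that feeds the
mitral valve.  Units are mmHg, ml and s throughout; flows cross into L/min
only at the I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from scipy.optimize import brentq

from . import _kernel


@dataclass
class AorticPVLaw:
    """Arterial pressure-volume law derived from the vessel stiffness parameter.

    The silicone aorta follows the pressure-diameter stiffness law
    ``ln(P/Ps) = beta * (D/Ds - 1)``.  Treating the segment as a tube of fixed
    length (``D`` proportional to ``sqrt(V)``) recasts it as a volume law
    ``ln(P/Ps) = beta * (sqrt(V/Vs) - 1)`` with ``Vs = ref_volume`` the volume
    held at the conventional reference pressure ``Ps = 100 mmHg``.
    """

    beta: float = 6.0
    ref_pressure: float = 100.0  # mmHg
    ref_volume: float = 300.0    # ml at ref_pressure

    def __post_init__(self):
        if self.beta <= 0 or self.ref_pressure <= 0 or self.ref_volume <= 0:
            raise ValueError("aortic P-V law parameters must be positive")


@dataclass
class CircuitParameters:
    """Resistances, compliances and volumes of the vascular network.

    The two clamped branches (peripheral/iliac and brachiocephalic) may carry
    a quadratic orifice loss ``k * q * |q|`` on top of their linear
    resistance, mirroring the tube clamps used to set them on the bench; the
    quadratic coefficients default to 0 (purely linear network).
    """

    r_systemic: float       # mmHg*s/ml, peripheral (iliac) resistance
    r_brachio: float        # mmHg*s/ml, brachiocephalic clamp
    r_aortic_seg: float     # mmHg*s/ml, ascending->descending segment
    c_venous: float         # ml/mmHg, venous reservoir + elastic vessel
    aortic_pv_law: AorticPVLaw = field(default_factory=AorticPVLaw)
    k_systemic: float = 0.0  # mmHg*s^2/ml^2, clamp orifice loss
    k_brachio: float = 0.0   # mmHg*s^2/ml^2
    l_aortic: float = 0.0   # mmHg*s^2/ml, aortic segment inertance (unused at 0)
    c_distal: float = 0.3   # ml/mmHg, distal-arterial (iliac junction) node
    v_unstressed_art: float = 0.0   # ml
    v_unstressed_dist: float = 50.0  # ml
    v_unstressed_ven: float = 2800.0  # ml
    v_total: float = 4000.0  # ml circulating volume; sets the MCFP

    def __post_init__(self):
        for name in ("r_systemic", "r_brachio", "r_aortic_seg", "c_venous",
                     "c_distal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_systemic < 0 or self.k_brachio < 0 or self.l_aortic < 0:
            raise ValueError("k_systemic, k_brachio, l_aortic must be >= 0")
        if self.v_total <= self.unstressed_volume():
            raise ValueError("v_total must exceed total unstressed volume")

    def unstressed_volume(self) -> float:
        return (self.v_unstressed_art + self.v_unstressed_dist
                + self.v_unstressed_ven)


@dataclass
class NetworkState:
    """Instantaneous state of the closed loop (the ODE state vector)."""

    v_lv: float
    v_art: float
    v_dist: float
    v_ven: float

    def total_volume(self) -> float:
        return self.v_lv + self.v_art + self.v_dist + self.v_ven


def arterial_pressure(v_art: float, law: AorticPVLaw) -> float:
    """Arterial pressure (mmHg) at stressed volume ``v_art`` (ml).

    Strictly increasing and smooth in ``v_art``; equals ``law.ref_pressure``
    at ``law.ref_volume``.
    """
    if v_art < 0:
        raise ValueError("negative transmural arterial volume")
    return float(_kernel.arterial_pressure_raw(
        v_art, law.beta, law.ref_pressure, law.ref_volume))


def arterial_volume(p: float, law: AorticPVLaw) -> float:
    """Inverse of :func:`arterial_pressure`; clamps to 0 below the law's range."""
    if p <= 0:
        return 0.0
    x = 1.0 + math.log(p / law.ref_pressure) / law.beta
    if x <= 0:
        return 0.0
    return law.ref_volume * x * x


def static_volumes(p: float, params: CircuitParameters,
                   elastance=None) -> NetworkState:
    """Compartment volumes when the whole loop sits at uniform pressure ``p``.

    ``elastance`` (an :class:`~mcsloop.ventricle.ElastanceParameters`) supplies
    the relaxed-ventricle P-V law; without it the ventricle is excluded (its
    content is treated as part of the conduit dead volume).
    """
    v_lv = 0.0
    if elastance is not None:
        v_lv = elastance.v0 + p / elastance.e_min
    v_art = params.v_unstressed_art + arterial_volume(p, params.aortic_pv_law)
    v_dist = params.v_unstressed_dist + params.c_distal * p
    v_ven = params.v_unstressed_ven + params.c_venous * p
    return NetworkState(v_lv=v_lv, v_art=v_art, v_dist=v_dist, v_ven=v_ven)


def compute_mcfp(params: CircuitParameters, elastance=None) -> float:
    """Mean circulatory filling pressure: the uniform zero-flow pressure.

    Distributes ``params.v_total`` across the compartment P-V laws.  Returns
    0 (with a warning) if the circulating volume does not exceed the total
    unstressed volume.
    """

    def excess(p):
        return static_volumes(p, params, elastance).total_volume() - params.v_total

    if excess(1e-9) >= 0.0:
        warnings.warn("v_total at or below total unstressed volume; MCFP = 0",
                      stacklevel=2)
        return 0.0
    p_hi = 500.0
    while excess(p_hi) < 0.0:
        p_hi *= 2.0
        if p_hi > 1e6:
            raise RuntimeError("MCFP search failed to bracket")
    return float(brentq(excess, 1e-9, p_hi, xtol=1e-10))


def set_volume_for_mcfp(params: CircuitParameters, target_mcfp: float,
                        elastance=None) -> float:
    """Circulating volume that produces ``target_mcfp`` (inverse of compute_mcfp).

    The static laws are analytically invertible, so this evaluates the sum of
    compartment volumes at the target pressure directly; the round trip agrees
    with :func:`compute_mcfp` to well under 0.01 mmHg.
    """
    if target_mcfp <= 0:
        raise ValueError("target MCFP must be > 0")
    v = static_volumes(target_mcfp, params, elastance).total_volume()
    if v <= params.unstressed_volume():
        raise ValueError("target MCFP unattainable with these laws")
    return float(v)
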