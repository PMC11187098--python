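"""Arterial stiffness law, MCFP statics and their inverses."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import bisect

from mcsloop import (AorticPVLaw, CircuitParameters, arterial_pressure,
                     arterial_volume, compute_mcfp, set_volume_for_mcfp)
from mcsloop.ventricle import ElastanceParameters

LAW = AorticPVLaw(beta=6.0, ref_pressure=100.0, ref_volume=300.0)


def make_circuit(**kw):
    base = dict(r_systemic=0.5, r_brachio=5.0, r_aortic_seg=0.1,
                c_venous=80.0, aortic_pv_law=LAW, v_unstressed_ven=2800.0,
                v_total=3600.0)
    base.update(kw)
    return CircuitParameters(**base)


def test_reference_point_identity():
    assert arterial_pressure(LAW.ref_volume, LAW) == pytest.approx(100.0)


def test_stiffness_law_inverse_at_20_percent_pressure_rise():
    # ln(P/Ps) = beta (D/Ds - 1) with D ~ sqrt(V): at P/Ps = 1.2 and beta 6
    # the diameter ratio must be 1 + ln(1.2)/6
    v = arterial_volume(120.0, LAW)
    d_ratio = math.sqrt(v / LAW.ref_volume)
    assert d_ratio == pytest.approx(1.0 + math.log(1.2) / 6.0, rel=1e-12)
    assert arterial_pressure(v, LAW) == pytest.approx(120.0, rel=1e-12)


@given(st.floats(min_value=50.0, max_value=900.0),
       st.floats(min_value=1.0, max_value=100.0))
def test_arterial_pressure_strictly_increasing(v, dv):
    assert arterial_pressure(v + dv, LAW) > arterial_pressure(v, LAW)


def test_stiffness_grows_with_pressure():
    # convexity: dP/dV evaluated at a higher pressure exceeds that at a lower
    eps = 1e-4
    v1, v2 = arterial_volume(60.0, LAW), arterial_volume(110.0, LAW)
    s1 = (arterial_pressure(v1 + eps, LAW) - arterial_pressure(v1, LAW)) / eps
    s2 = (arterial_pressure(v2 + eps, LAW) - arterial_pressure(v2, LAW)) / eps
    assert s2 > s1


def test_negative_volume_rejected():
    with pytest.raises(ValueError):
        arterial_pressure(-1.0, LAW)


def test_mcfp_of_packaged_calibrations(packaged_params):
    # the bench sets MCFP to 7 mmHg (normal) and 13 mmHg (shock) by fluid fill
    for cond, target in (("normal", 7.0), ("cs", 13.0)):
        lp = packaged_params[cond]
        assert compute_mcfp(lp.circuit, lp.elastance) == pytest.approx(
            target, abs=0.01)


def test_mcfp_increases_with_volume():
    el = ElastanceParameters(e_max=0.8, e_min=0.1, v0=60.0)
    p = [compute_mcfp(make_circuit(v_total=v), el)
         for v in (3200.0, 3500.0, 3900.0)]
    assert p[0] < p[1] < p[2]


def test_mcfp_zero_with_warning_below_unstressed():
    # circulating volume above the vascular unstressed volume but below the
    # relaxed-ventricle content: no positive filling pressure exists
    el = ElastanceParameters(e_max=0.8, e_min=0.1, v0=60.0)
    ci = make_circuit(v_total=2851.0)  # unstressed 2850, v0 = 60
    with pytest.warns(UserWarning):
        assert compute_mcfp(ci, el) == 0.0
    assert compute_mcfp(make_circuit(v_total=3000.0), el) > 0.0


@pytest.mark.filterwarnings("ignore:v_total at or below")
@pytest.mark.parametrize("target", [5.0, 10.0, 15.0])
def test_volume_for_mcfp_round_trip_matches_bisection(target):
    el = ElastanceParameters(e_max=0.8, e_min=0.1, v0=60.0)
    v = set_volume_for_mcfp(make_circuit(), target, el)
    ci = make_circuit(v_total=v)
    assert compute_mcfp(ci, el) == pytest.approx(target, abs=0.01)
    # independent oracle: bisection on the forward map over total volume
    f = lambda vt: compute_mcfp(make_circuit(v_total=vt), el) - target
    v_oracle = bisect(f, 2900.0, 20000.0, xtol=1e-6)
    assert v == pytest.approx(v_oracle, abs=1e-3)


def test_volume_for_mcfp_monotone_and_errors():
    el = ElastanceParameters(e_max=0.8, e_min=0.1, v0=60.0)
    v7 = set_volume_for_mcfp(make_circuit(), 7.0, el)
    v13 = set_volume_for_mcfp(make_circuit(), 13.0, el)
    assert v13 > v7
    with pytest.raises(ValueError):
        set_volume_for_mcfp(make_circuit(), -1.0, el)


def test_parameter_invariants_enforced():
    with pytest.raises(ValueError):
        make_circuit(r_systemic=-0.1)
    with pytest.raises(ValueError):
        make_circuit(v_total=100.0)  # below unstressed volume
    with pytest.raises(ValueError):
        AorticPVLaw(beta=-1.0)
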