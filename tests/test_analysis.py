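"""Waveform metrics: pressure summaries, P-V loop indices, flow bookkeeping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcsloop import (classify_aortic_flow, flow_summary, pressure_summary,
                     pv_metrics)

from conftest import synthetic_result


def test_pressure_summary_constant():
    assert pressure_summary(np.full(800, 54.0)) == pytest.approx(
        (54.0, 54.0, 54.0))


def test_pressure_summary_sinusoid_closed_form():
    # 54 + 21 sin(2 pi 1.25 t): systolic 75, diastolic 33, mean 54
    t = np.arange(0, 1.6, 1e-4)
    p = 54.0 + 21.0 * np.sin(2 * np.pi * 1.25 * t)
    s, d, m = pressure_summary(p, samples_per_beat=8000)
    assert s == pytest.approx(75.0, abs=0.01)
    assert d == pytest.approx(33.0, abs=0.01)
    assert m == pytest.approx(54.0, abs=0.01)


@given(st.lists(st.floats(min_value=-50, max_value=250), min_size=4,
                max_size=64))
def test_pressure_summary_ordering(vals):
    s, d, m = pressure_summary(np.array(vals))
    assert d <= m + 1e-9 <= s + 2e-9


def test_pressure_summary_empty_errors():
    with pytest.raises(ValueError):
        pressure_summary(np.array([]))


def _rectangle_loop(n=400, edv=150.0, esv=100.0, p_lo=10.0, p_hi=110.0):
    """Rectangular P-V loop traced counter-clockwise in (V, P)."""
    q = n // 4
    v = np.concatenate([np.full(q, edv), np.linspace(edv, esv, q),
                        np.full(q, esv), np.linspace(esv, edv, q)])
    p = np.concatenate([np.linspace(p_lo, p_hi, q), np.full(q, p_hi),
                        np.linspace(p_hi, p_lo, q), np.full(q, p_lo)])
    return v, p


def test_pv_metrics_on_rectangular_loop():
    v, p = _rectangle_loop()
    res = synthetic_result(np.arange(len(v)) * 1e-3, p_lv=p, v_lv=v)
    m = pv_metrics(res, v0=20.0)
    assert m.edv == pytest.approx(150.0)
    assert m.esv == pytest.approx(100.0)
    assert m.sv == pytest.approx(m.edv - m.esv)  # identity by construction
    assert m.peak_vp == pytest.approx(110.0)
    area = 50.0 * 100.0
    assert m.stroke_work == pytest.approx(area, rel=0.02)
    # PVA adds the end-systolic triangle 0.5 * ESP * (ESV - V0)
    esp = m.pva - m.stroke_work
    assert esp == pytest.approx(0.5 * 110.0 * (100.0 - 20.0), rel=0.05)
    assert m.pva >= m.stroke_work >= 0.0
    assert not m.degenerate


def test_pv_metrics_constant_volume_degenerate():
    n = 200
    res = synthetic_result(np.arange(n) * 1e-3, p_lv=np.full(n, 30.0),
                           v_lv=np.full(n, 150.0))
    m = pv_metrics(res, v0=20.0)
    assert m.sv == 0.0
    assert m.degenerate


def test_pv_metrics_requires_convergence():
    n = 100
    res = synthetic_result(np.arange(n) * 1e-3, v_lv=np.full(n, 1.0))
    res.converged = False
    with pytest.raises(ValueError):
        pv_metrics(res)


@pytest.mark.parametrize("q, expected", [
    (-0.27, "retrograde"),   # maximum ECMO, no Impella
    (-0.05, "stagnant"),     # the near-zero watershed
    (-0.10, "stagnant"),
    (0.07, "stagnant"),
    (0.60, "antegrade"),
])
def test_flow_direction_classification(q, expected):
    assert classify_aortic_flow(q) == expected


def test_flow_classification_band_configurable():
    assert classify_aortic_flow(-0.2, stagnation_band=0.25) == "stagnant"
    assert classify_aortic_flow(-0.2, stagnation_band=0.1) == "retrograde"


def test_flow_summary_total_and_brachio_fraction():
    # printed normal baseline: aorta 4.3, brachio 0.6 -> 12.2% of output
    n = 800
    res = synthetic_result(
        np.arange(n) * 1e-3,
        q_aorta_desc=np.full(n, 4.3 / 0.06),
        q_brachio=np.full(n, 0.6 / 0.06),
        q_iliac=np.full(n, 4.3 / 0.06),
        p_ao=np.full(n, 88.0))
    hs = flow_summary(res)
    assert hs.q_total_mean == pytest.approx(hs.q_iliac_mean
                                            + hs.q_brachio_mean)
    assert hs.brachio_fraction == pytest.approx(12.2, abs=0.05)
    assert hs.aortic_flow_class == "antegrade"
    # shock baseline share: 0.4 / (2.8 + 0.4) = 12.5%
    res2 = synthetic_result(
        np.arange(n) * 1e-3,
        q_aorta_desc=np.full(n, 2.8 / 0.06),
        q_brachio=np.full(n, 0.4 / 0.06),
        q_iliac=np.full(n, 2.8 / 0.06))
    assert flow_summary(res2).brachio_fraction == pytest.approx(12.5,
                                                                abs=0.05)


def test_flow_summary_zero_flow_flagged():
    n = 100
    hs = flow_summary(synthetic_result(np.arange(n) * 1e-3))
    assert hs.q_total_mean == 0.0
    assert not hs.brachio_fraction_defined
    assert hs.brachio_fraction == 0.0
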