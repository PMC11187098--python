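"""Hemodynamic and pressure-volume loop metrics at the bench probe sites.

Conventions follow the conductance-catheter literature: end-diastole is the
maximum-volume instant of a beat (mitral closure), end-systole the
minimum-volume instant; stroke volume is EDV - ESV by construction.  Ees is
model-based — the line through the end-systolic point and (V0, 0) — since no
preload-variation runs exist per scenario.  PVA is stroke work (loop area)
plus the end-systolic potential-energy triangle.

Flows are cycle means converted to L/min; "total flow" is iliac plus
brachiocephalic flow, matching the bench bookkeeping, and the brachiocephalic
fraction uses (aortic probe + brachiocephalic) as the denominator, which is
what reproduces the printed 12.2% / 12.5% shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

ML_S_TO_L_MIN = 0.06


@dataclass
class PVLoopMetrics:
    peak_vp: float   # mmHg
    edp: float       # mmHg
    edv: float       # ml
    esv: float       # ml
    sv: float        # ml (= edv - esv exactly)
    ees: float       # mmHg/ml
    ea: float        # mmHg/ml
    pva: float       # mmHg*ml per beat
    stroke_work: float  # mmHg*ml per beat
    degenerate: bool = False


@dataclass
class HemoSummary:
    p_ao_sys: float
    p_ao_dia: float
    p_ao_mean: float
    p_vr_mean: float
    q_aorta_mean: float    # L/min, descending-aorta probe
    q_iliac_mean: float    # L/min
    q_brachio_mean: float  # L/min
    q_total_mean: float    # L/min (= iliac + brachio)
    brachio_fraction: float  # % of (aorta + brachio)
    brachio_fraction_defined: bool
    aortic_flow_class: str


def _beats(x: np.ndarray, samples_per_beat: int) -> np.ndarray:
    n = (len(x) // samples_per_beat) * samples_per_beat
    if n == 0:
        raise ValueError("need at least one full beat")
    return np.asarray(x[:n]).reshape(-1, samples_per_beat)


def pressure_summary(p, samples_per_beat: Optional[int] = None
                     ) -> Tuple[float, float, float]:
    """(systolic, diastolic, mean): per-beat max / per-beat min averaged over
    beats, and the time average — the tables' "s/d (m)" notation."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty pressure series")
    if samples_per_beat is None:
        samples_per_beat = p.size
    b = _beats(p, samples_per_beat)
    return (float(b.max(axis=1).mean()), float(b.min(axis=1).mean()),
            float(b.mean()))


def pv_metrics(result, v0: Optional[float] = None,
               require_converged: bool = True) -> PVLoopMetrics:
    """Pressure-volume loop indices averaged over the recorded beats."""
    if require_converged and not result.converged:
        raise ValueError("pv_metrics requires a converged (periodic) result")
    if v0 is None:
        v0 = result.v0
    v = _beats(result.v_lv, result.samples_per_beat)
    p = _beats(result.p_lv, result.samples_per_beat)

    i_ed = v.argmax(axis=1)
    i_es = v.argmin(axis=1)
    rows = np.arange(v.shape[0])
    edv = v[rows, i_ed]
    esv = v[rows, i_es]
    edp = p[rows, i_ed]
    esp = p[rows, i_es]
    peak = p.max(axis=1)
    sv = edv - esv

    # stroke work: shoelace area of the closed (V, P) loop per beat
    area = np.empty(v.shape[0])
    for k in range(v.shape[0]):
        vv, pp = v[k], p[k]
        area[k] = abs(0.5 * np.sum(vv * np.roll(pp, -1) - np.roll(vv, -1) * pp))

    degenerate = bool(np.any(sv <= 1e-9))
    with np.errstate(divide="ignore", invalid="ignore"):
        ees = np.where(esv - v0 > 0, esp / np.maximum(esv - v0, 1e-12), np.inf)
        ea = np.where(sv > 0, esp / np.maximum(sv, 1e-12), np.inf)
    pe = 0.5 * esp * np.maximum(esv - v0, 0.0)
    pva = area + pe

    def m(x):
        return float(np.mean(x))

    return PVLoopMetrics(
        peak_vp=m(peak), edp=m(edp), edv=m(edv), esv=m(esv), sv=m(sv),
        ees=m(ees) if np.all(np.isfinite(ees)) else float("inf"),
        ea=m(ea) if np.all(np.isfinite(ea)) else float("inf"),
        pva=m(pva), stroke_work=m(area), degenerate=degenerate)


def classify_aortic_flow(q_aorta_mean: float,
                         stagnation_band: float = 0.15) -> str:
    """Direction class of the mean descending-aortic flow (L/min).

    The stagnation band (default +/-0.15 L/min) flags the watershed regime in
    which retrograde ECMO return meets antegrade ejection and the probe reads
    near zero — the thrombosis-risk pattern discussed for high ECMO support.
    """
    if q_aorta_mean < -stagnation_band:
        return "retrograde"
    if q_aorta_mean > stagnation_band:
        return "antegrade"
    return "stagnant"


def flow_summary(result, stagnation_band: float = 0.15) -> HemoSummary:
    """Cycle-mean pressures and site flows of a converged simulation."""
    ps, pd_, pm = pressure_summary(result.p_ao, result.samples_per_beat)
    q_ao = float(np.mean(result.q_aorta_desc)) * ML_S_TO_L_MIN
    q_il = float(np.mean(result.q_iliac)) * ML_S_TO_L_MIN
    q_br = float(np.mean(result.q_brachio)) * ML_S_TO_L_MIN
    denom = q_ao + q_br
    defined = abs(denom) > 1e-9
    frac = 100.0 * q_br / denom if defined else 0.0
    return HemoSummary(
        p_ao_sys=ps, p_ao_dia=pd_, p_ao_mean=pm,
        p_vr_mean=float(np.mean(result.p_vr)),
        q_aorta_mean=q_ao, q_iliac_mean=q_il, q_brachio_mean=q_br,
        q_total_mean=q_il + q_br,
        brachio_fraction=frac, brachio_fraction_defined=defined,
        aortic_flow_class=classify_aortic_flow(q_ao, stagnation_band))


def plot_pv_loop(result, ax=None, **kwargs):
    """P-V loop (volume on x, pressure on y) of the recorded beats."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.v_lv, result.p_lv, **kwargs)
    ax.set_xlabel("LV volume (ml)")
    ax.set_ylabel("LV pressure (mmHg)")
    return ax
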