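"""Numba-compiled core of the closed-loop model.

Everything here works on a flat float64 parameter vector (layout below) and a
4-element state vector ``y = [v_lv, v_art, v_dist, v_ven]`` in mmHg / ml / s
units: ventricle, aortic-arch node (nonlinear stiffness-law compliance),
distal-arterial node (small linear compliance at the iliac/ECMO-return
junction) and venous reservoir.  The clamped branches (peripheral and
brachiocephalic) carry an optional quadratic orifice loss on top of their
linear resistance, mirroring the tube clamps of the physical loop.

The ventricular activation waveform is pre-tabulated per beat on the RK4
half-step grid (it is strictly periodic), which keeps transcendental calls
out of the inner loop.
"""

import math

import numpy as np
from numba import njit

# -- parameter-vector layout -------------------------------------------------
HR = 0        # beats/min
EMAX = 1      # mmHg/ml
EMIN = 2      # mmHg/ml
V0 = 3        # ml
TSYS = 4      # systolic fraction of the cycle (informational; act grid encodes it)
RMV = 5       # mitral forward resistance, mmHg*s/ml
RAOV = 6      # aortic-valve forward resistance
SMOOTH = 7    # valve diode smoothing half-width, mmHg
BETA = 8      # arterial stiffness parameter (dimensionless)
PREF = 9      # arterial reference pressure, mmHg
VREF = 10     # arterial reference volume at PREF, ml
VUA = 11      # arterial unstressed volume, ml
CDIST = 12    # distal-arterial compliance, ml/mmHg
VUD = 13      # distal-arterial unstressed volume, ml
CVEN = 14     # venous compliance, ml/mmHg
VUV = 15      # venous unstressed volume, ml
RSYS = 16     # systemic (iliac/peripheral) linear resistance
KSYS = 17     # systemic quadratic (clamp orifice) loss, mmHg*s^2/ml^2
RBR = 18      # brachiocephalic linear resistance
KBR = 19      # brachiocephalic quadratic loss
RAO = 20      # ascending->descending aortic segment resistance
ICA = 21      # Impella head coefficient, mmHg/rpm^2
ICB = 22      # Impella internal loss, mmHg*s^2/ml^2
IRC = 23      # Impella cannula resistance, mmHg*s/ml
IRPM = 24     # Impella speed, rpm
SUCTHR = 25   # suction-guard threshold LV pressure, mmHg
SUCLOW = 26   # suction-guard full-derating LV pressure, mmHg
ECA = 27      # ECMO head coefficient, mmHg/rpm^2
ECB = 28      # ECMO internal loss, mmHg*s^2/ml^2
ERC = 29      # ECMO circuit resistance, mmHg*s/ml
ERPM = 30     # ECMO speed, rpm
VTOT = 31     # total circulating volume, ml
NPAR = 32

# double-Hill activation shape exponents (Stergiopulos-type normalized elastance)
HILL_N1 = 1.9
HILL_N2 = 21.9


@njit(cache=True)
def activation_raw(tau, t_sys):
    """Un-normalized double-Hill activation at cycle phase tau in [0, 1)."""
    a1 = 0.5 * t_sys
    a2 = t_sys
    x1 = (tau / a1) ** HILL_N1
    x2 = (tau / a2) ** HILL_N2
    return (x1 / (1.0 + x1)) / (1.0 + x2)


@njit(cache=True)
def diode_flow(dp, r, s):
    """One-way valve flow: zero for dp <= 0, C1 quadratic blend over [0, s]."""
    if dp <= 0.0:
        return 0.0
    if s > 0.0 and dp < s:
        return dp * dp / (2.0 * s * r)
    return (dp - 0.5 * s) / r


@njit(cache=True)
def arterial_pressure_raw(v, beta, pref, vref):
    """Stiffness-law arterial pressure from stressed volume v (constant-length tube)."""
    x = math.sqrt(max(v, 1e-12) / vref) - 1.0
    return pref * math.exp(beta * x)


@njit(cache=True)
def branch_flow(dp, r, k):
    """Signed flow through a linear + quadratic (orifice) resistance."""
    if k <= 0.0:
        return dp / r
    a = abs(dp)
    q = (-r + math.sqrt(r * r + 4.0 * k * a)) / (2.0 * k)
    return q if dp >= 0.0 else -q


@njit(cache=True)
def pump_flow_root(head_avail, cb, rlin):
    """Positive root of cb*q^2 + rlin*q = head_avail; 0 if no positive root."""
    if head_avail <= 0.0:
        return 0.0
    if cb <= 0.0:
        return head_avail / rlin
    return (-rlin + math.sqrt(rlin * rlin + 4.0 * cb * head_avail)) / (2.0 * cb)


@njit(cache=True)
def suction_factor(p_lv, thr, low):
    if p_lv >= thr:
        return 1.0
    if p_lv <= low:
        return 0.0
    return (p_lv - low) / (thr - low)


@njit(cache=True)
def _signals(e_act, y0, y1, y2, y3, pv):
    """All node pressures, branch flows and state derivatives at one instant.

    State: y0 = v_lv, y1 = v_art, y2 = v_dist, y3 = v_ven.
    Returns (p_lv, p_ao, p_d, p_ven, q_mv, q_aov, q_imp, q_ec, q_ad, q_br,
    q_il, d_vlv, d_vart, d_vdist, d_vven).
    """
    e = pv[EMIN] + (pv[EMAX] - pv[EMIN]) * e_act
    p_lv = e * (y0 - pv[V0])
    p_ao = arterial_pressure_raw(y1 - pv[VUA], pv[BETA], pv[PREF], pv[VREF])
    p_d = (y2 - pv[VUD]) / pv[CDIST]
    p_ven = (y3 - pv[VUV]) / pv[CVEN]

    s = pv[SMOOTH]
    q_mv = diode_flow(p_ven - p_lv, pv[RMV], s)
    q_aov = diode_flow(p_lv - p_ao, pv[RAOV], s)

    q_imp = 0.0
    if pv[IRPM] > 0.0:
        head = pv[ICA] * pv[IRPM] * pv[IRPM] - (p_ao - p_lv)
        q_imp = pump_flow_root(head, pv[ICB], pv[IRC])
        q_imp *= suction_factor(p_lv, pv[SUCTHR], pv[SUCLOW])

    q_ec = 0.0
    if pv[ERPM] > 0.0:
        head = pv[ECA] * pv[ERPM] * pv[ERPM] - (p_d - p_ven)
        q_ec = pump_flow_root(head, pv[ECB], pv[ERC])

    q_ad = (p_ao - p_d) / pv[RAO]
    q_br = branch_flow(p_ao - p_ven, pv[RBR], pv[KBR])
    q_il = branch_flow(p_d - p_ven, pv[RSYS], pv[KSYS])

    d_vlv = q_mv - q_aov - q_imp
    d_vart = q_aov + q_imp - q_br - q_ad
    d_vdist = q_ad + q_ec - q_il
    d_vven = q_br + q_il - q_mv - q_ec
    return (p_lv, p_ao, p_d, p_ven, q_mv, q_aov, q_imp, q_ec, q_ad, q_br,
            q_il, d_vlv, d_vart, d_vdist, d_vven)


@njit(cache=True)
def _derivs(e_act, y0, y1, y2, y3, pv):
    sig = _signals(e_act, y0, y1, y2, y3, pv)
    return sig[11], sig[12], sig[13], sig[14]


@njit(cache=True)
def beat_map(y, pv, act, nsteps, dt):
    """Advance the state by one full beat with fixed-step RK4 (in place).

    ``act`` holds the normalized activation on the half-step grid
    (length 2*nsteps + 1: act[2*i] at t_i, act[2*i+1] at t_i + dt/2).
    """
    y0, y1, y2, y3 = y[0], y[1], y[2], y[3]
    for i in range(nsteps):
        e1 = act[2 * i]
        e2 = act[2 * i + 1]
        e3 = act[2 * i + 2]
        a0, a1, a2, a3 = _derivs(e1, y0, y1, y2, y3, pv)
        b0, b1, b2, b3 = _derivs(e2, y0 + 0.5 * dt * a0, y1 + 0.5 * dt * a1,
                                 y2 + 0.5 * dt * a2, y3 + 0.5 * dt * a3, pv)
        c0, c1, c2, c3 = _derivs(e2, y0 + 0.5 * dt * b0, y1 + 0.5 * dt * b1,
                                 y2 + 0.5 * dt * b2, y3 + 0.5 * dt * b3, pv)
        d0, d1, d2, d3 = _derivs(e3, y0 + dt * c0, y1 + dt * c1,
                                 y2 + dt * c2, y3 + dt * c3, pv)
        y0 += dt * (a0 + 2.0 * b0 + 2.0 * c0 + d0) / 6.0
        y1 += dt * (a1 + 2.0 * b1 + 2.0 * c1 + d1) / 6.0
        y2 += dt * (a2 + 2.0 * b2 + 2.0 * c2 + d2) / 6.0
        y3 += dt * (a3 + 2.0 * b3 + 2.0 * c3 + d3) / 6.0
    y[0], y[1], y[2], y[3] = y0, y1, y2, y3
    return y


# columns of the recording buffer
REC_COLS = ("time_s", "p_lv_mmHg", "p_ao_mmHg", "p_distal_mmHg", "p_vr_mmHg",
            "v_lv_ml", "v_art_ml", "v_dist_ml", "v_ven_ml",
            "q_mv_ml_per_s", "q_aov_ml_per_s", "q_impella_ml_per_s",
            "q_ecmo_ml_per_s", "q_aorta_desc_ml_per_s", "q_brachio_ml_per_s",
            "q_iliac_ml_per_s")
NREC = 16


@njit(cache=True)
def beat_record(y, pv, act, nsteps, dt, stride, out, row0, t0):
    """One beat of RK4 identical to beat_map, sampling every ``stride`` steps.

    Writes rows of REC_COLS into ``out`` starting at ``row0``; returns the
    number of rows written.
    """
    y0, y1, y2, y3 = y[0], y[1], y[2], y[3]
    nrow = 0
    for i in range(nsteps):
        e1 = act[2 * i]
        if i % stride == 0:
            sig = _signals(e1, y0, y1, y2, y3, pv)
            r = row0 + nrow
            out[r, 0] = t0 + i * dt
            out[r, 1] = sig[0]
            out[r, 2] = sig[1]
            out[r, 3] = sig[2]
            out[r, 4] = sig[3]
            out[r, 5] = y0
            out[r, 6] = y1
            out[r, 7] = y2
            out[r, 8] = y3
            out[r, 9] = sig[4]
            out[r, 10] = sig[5]
            out[r, 11] = sig[6]
            out[r, 12] = sig[7]
            out[r, 13] = sig[8]
            out[r, 14] = sig[9]
            out[r, 15] = sig[10]
            nrow += 1
        e2 = act[2 * i + 1]
        e3 = act[2 * i + 2]
        a0, a1, a2, a3 = _derivs(e1, y0, y1, y2, y3, pv)
        b0, b1, b2, b3 = _derivs(e2, y0 + 0.5 * dt * a0, y1 + 0.5 * dt * a1,
                                 y2 + 0.5 * dt * a2, y3 + 0.5 * dt * a3, pv)
        c0, c1, c2, c3 = _derivs(e2, y0 + 0.5 * dt * b0, y1 + 0.5 * dt * b1,
                                 y2 + 0.5 * dt * b2, y3 + 0.5 * dt * b3, pv)
        d0, d1, d2, d3 = _derivs(e3, y0 + dt * c0, y1 + dt * c1,
                                 y2 + dt * c2, y3 + dt * c3, pv)
        y0 += dt * (a0 + 2.0 * b0 + 2.0 * c0 + d0) / 6.0
        y1 += dt * (a1 + 2.0 * b1 + 2.0 * c1 + d1) / 6.0
        y2 += dt * (a2 + 2.0 * b2 + 2.0 * c2 + d2) / 6.0
        y3 += dt * (a3 + 2.0 * b3 + 2.0 * c3 + d3) / 6.0
    y[0], y[1], y[2], y[3] = y0, y1, y2, y3
    return nrow


def activation_grid(t_sys, nsteps):
    """Normalized activation tabulated on the RK4 half-step grid of one beat."""
    tau = np.arange(2 * nsteps + 1) / (2.0 * nsteps)
    tau[-1] = 0.0  # wrap: t = T is phase 0 of the next beat
    a1 = 0.5 * t_sys
    a2 = t_sys
    x1 = (tau / a1) ** HILL_N1
    x2 = (tau / a2) ** HILL_N2
    raw = (x1 / (1.0 + x1)) / (1.0 + x2)
    return raw / activation_peak(t_sys)


def activation_peak(t_sys):
    """Maximum of the raw double-Hill waveform (normalization constant)."""
    tau = np.linspace(0.0, 1.0, 4001)
    a1 = 0.5 * t_sys
    a2 = t_sys
    x1 = (tau / a1) ** HILL_N1
    x2 = (tau / a2) ** HILL_N2
    return float(((x1 / (1.0 + x1)) / (1.0 + x2)).max())
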