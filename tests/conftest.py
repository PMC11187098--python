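import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from mcsloop import (AorticPVLaw, CircuitParameters, EcmoParameters,
                     ElastanceParameters, ImpellaParameters, LoopParameters,
                     ValveParameters, set_volume_for_mcfp)


def nominal_loop(condition="cs", with_devices=True, mcfp=13.0,
                 e_max=0.8) -> LoopParameters:
    """A physically plausible, hand-set parameter bundle for physics tests
    (independent of any calibration output)."""
    law = AorticPVLaw(beta=6.0, ref_pressure=100.0, ref_volume=300.0)
    el = ElastanceParameters(e_max=e_max, e_min=0.1, v0=60.0,
                             t_sys_frac=0.3, hr=75.0)
    ci = CircuitParameters(
        r_systemic=0.5, k_systemic=0.008, r_brachio=5.0, k_brachio=0.3,
        r_aortic_seg=0.1, c_venous=80.0, aortic_pv_law=law,
        v_unstressed_ven=2800.0, v_total=3600.0)
    from dataclasses import replace
    ci = replace(ci, v_total=set_volume_for_mcfp(ci, mcfp, el))
    lp = LoopParameters(
        circuit=ci, elastance=el,
        mitral=ValveParameters(0.01, 0.3),
        aortic_valve=ValveParameters(0.05, 0.3), condition=condition)
    if with_devices:
        lp.impella = ImpellaParameters(c_speed=5e-8, c_flow=0.02,
                                       r_cannula=0.1)
        lp.ecmo = EcmoParameters(c_speed=2e-5, c_flow=0.02, r_circuit=0.3)
    return lp


@pytest.fixture(scope="session")
def nominal_cs():
    return nominal_loop()


@pytest.fixture(scope="session")
def packaged_params():
    """The shipped calibration output (one LoopParameters per condition)."""
    from importlib import resources
    from mcsloop import load_parameters
    out = {}
    for cond in ("normal", "cs"):
        with resources.as_file(resources.files("mcsloop.data")
                               / f"params_{cond}.yaml") as p:
            out[cond] = load_parameters(p)
    return out


@pytest.fixture(scope="session")
def reference_df():
    from mcsloop import load_reference_frame
    return load_reference_frame()


@pytest.fixture(scope="session")
def calibrated_model():
    """Full two-stage calibration, run once per session (deterministic)."""
    from mcsloop import run_full_calibration
    return run_full_calibration()


@pytest.fixture(scope="session")
def holdout_predictions(calibrated_model):
    from mcsloop import predict_holdout
    return predict_holdout(calibrated_model)


def synthetic_result(time, p_lv=None, v_lv=None, samples_per_beat=None,
                     **waves):
    """Assemble a SimulationResult from hand-built waveforms for the
    analysis layer (everything unspecified is zero)."""
    from mcsloop import SimulationResult
    n = len(time)
    z = np.zeros(n)
    fields = dict(p_lv=z, p_ao=z, p_distal=z, p_vr=z, v_lv=z, v_art=z,
                  v_dist=z, v_ven=z, q_mv=z, q_aov=z, q_impella=z, q_ecmo=z,
                  q_aorta_desc=z, q_brachio=z, q_iliac=z)
    if p_lv is not None:
        fields["p_lv"] = np.asarray(p_lv, float)
    if v_lv is not None:
        fields["v_lv"] = np.asarray(v_lv, float)
    for k, v in waves.items():
        fields[k] = np.asarray(v, float)
    return SimulationResult(
        time=np.asarray(time, float), **fields, converged=True,
        periodicity_residual=0.0, beats_run=1,
        beats_recorded=max(1, n // (samples_per_beat or n)),
        samples_per_beat=samples_per_beat or n, hr=75.0, v0=20.0,
        v_total=float(np.nan))
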