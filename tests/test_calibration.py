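"""Calibration plumbing: specs, data splits, audit, determinism."""

import numpy as np
import pandas as pd
import pytest

from mcsloop import (CalibrationSpec, build_condition, default_baseline_spec,
                     default_pump_spec, scenario_metrics,
                     stage2_loop_parameters)
from mcsloop.calibration import MCFP_TARGET, STAGE1_PARAMS, STAGE2_PARAMS
from mcsloop.circuit import compute_mcfp

P1 = {k: v[0] for k, v in STAGE1_PARAMS.items()}
P2 = {k: v[0] for k, v in STAGE2_PARAMS.items()}


def test_objective_and_holdout_disjoint():
    for spec in (default_baseline_spec(), default_pump_spec()):
        keys = ["condition", "impella_level", "ecmo_rpm", "quantity",
                "source"]
        obj = set(map(tuple, spec.objective_records[keys].itertuples(False)))
        hold = set(map(tuple, spec.holdout_records[keys].itertuples(False)))
        assert obj and hold and not (obj & hold)


def test_overlapping_spec_rejected():
    df = default_baseline_spec().objective_records
    with pytest.raises(ValueError):
        CalibrationSpec({"x": (1, 0, 2)}, df, df)


def test_holdout_is_combination_only():
    spec = default_pump_spec()
    h = spec.holdout_records
    assert set(h.source) == {"table3", "table4"}
    assert (h.impella_level != "P0").all()
    assert (h.ecmo_rpm != 0).all()


def test_stage2_objective_excludes_anomaly_and_pv_quantities():
    obj = default_pump_spec().objective_records
    assert not obj.anomaly.any()
    assert set(obj.quantity) <= {"total_flow", "p_ao_sys", "p_ao_dia",
                                 "p_ao_mean", "p_vr_mean"}
    assert (obj[obj.source == "table1"].impella_level != "P0").all()
    assert (obj[obj.source == "table2"].ecmo_rpm != 0).all()


def test_build_condition_enforces_mcfp_and_shared_resistance():
    normal = build_condition(P1, "normal")
    cs = build_condition(P1, "cs")
    for lp, cond in ((normal, "normal"), (cs, "cs")):
        assert compute_mcfp(lp.circuit, lp.elastance) == pytest.approx(
            MCFP_TARGET[cond], abs=1e-6)
    # peripheral and branch resistances are condition-independent
    assert normal.circuit.r_systemic == cs.circuit.r_systemic
    assert normal.circuit.r_brachio == cs.circuit.r_brachio
    assert cs.circuit.v_total > normal.circuit.v_total  # 13 vs 7 mmHg fill


def test_stage2_loop_parameters_overrides_cvenous():
    lp = stage2_loop_parameters(P1, dict(P2, c_venous=25.0))
    assert lp.circuit.c_venous == 25.0
    assert compute_mcfp(lp.circuit, lp.elastance) == pytest.approx(13.0,
                                                                   abs=1e-6)
    assert lp.impella is not None and lp.ecmo is not None


def test_scenario_metrics_complete(nominal_cs):
    from mcsloop import Scenario, run_to_periodic
    m = scenario_metrics(run_to_periodic(Scenario(), nominal_cs))
    expected = {"total_flow", "q_aorta", "q_iliac", "q_brachio", "p_ao_sys",
                "p_ao_dia", "p_ao_mean", "p_vr_mean", "peak_lvp", "edp",
                "esv", "edv", "sv", "q_impella", "q_ecmo"}
    assert expected <= set(m)
    assert m["total_flow"] == pytest.approx(m["q_iliac"] + m["q_brachio"])


def test_fit_results_audited_and_within_bounds(calibrated_model):
    base = calibrated_model.baseline_fit
    pumps = calibrated_model.pump_fit
    # audit: the consumed record ids are exactly the objective sets
    assert all(k[4] == "results_baseline" for k in base.records_used)
    assert all(k[4] in ("table1", "table2") for k in pumps.records_used)
    assert base.within_bounds(default_baseline_spec())
    assert pumps.within_bounds(default_pump_spec())
    # deterministic multistart bookkeeping
    assert len(base.multistart_costs) == 3
    assert base.cost == pytest.approx(min(base.multistart_costs))
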