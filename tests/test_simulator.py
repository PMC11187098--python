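"""Closed-loop assembly, periodic convergence and conservation."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mcsloop import (Scenario, assemble_rhs, compute_mcfp, initial_state,
                     run_to_periodic, scenario_grid)
from mcsloop.simulator import pack_parameters, save_parameters, load_parameters

from conftest import nominal_loop


def test_rhs_conserves_volume_pointwise(nominal_cs):
    rhs = assemble_rhs(Scenario(impella_level="P6", ecmo_rpm=2000),
                       nominal_cs)
    rng = np.random.default_rng(7)
    for _ in range(20):
        y = np.array([rng.uniform(80, 250), rng.uniform(100, 400),
                      rng.uniform(40, 120), rng.uniform(2900, 3400)])
        assert abs(rhs(rng.uniform(0, 0.8), y).sum()) < 1e-9


def test_devices_off_means_inert_branches(nominal_cs):
    res = run_to_periodic(Scenario(), nominal_cs)
    assert np.all(res.q_impella == 0.0)
    assert np.all(res.q_ecmo == 0.0)


def test_equilibrium_state_has_zero_derivatives(nominal_cs):
    # uniform-MCFP state, activation at its diastolic zero
    rhs = assemble_rhs(Scenario(), nominal_cs)
    y = initial_state(nominal_cs)
    assert np.max(np.abs(rhs(0.0, y))) < 1e-9


def test_static_relaxation_to_mcfp():
    # drive (nearly) off, devices off: every node pressure settles at the MCFP
    lp = nominal_loop(with_devices=False)
    lp.elastance = dataclasses.replace(lp.elastance, e_max=0.1000001,
                                       e_min=0.1)
    y0 = initial_state(lp)
    y0[1] += 100.0  # perturb: shift volume artery <- reservoir
    y0[3] -= 100.0
    res = run_to_periodic(Scenario(), lp, y0=y0)
    mcfp = compute_mcfp(lp.circuit, lp.elastance)
    for p in (res.p_lv, res.p_ao, res.p_distal, res.p_vr):
        assert np.max(np.abs(p - mcfp)) < 0.1


def test_volume_conservation_along_trajectory(nominal_cs):
    res = run_to_periodic(Scenario(impella_level="P4", ecmo_rpm=1500),
                          nominal_cs)
    total = res.v_lv + res.v_art + res.v_dist + res.v_ven
    assert np.max(np.abs(total - res.v_total)) < 1e-6 * res.v_total


def test_periodic_convergence_and_residual(nominal_cs):
    res = run_to_periodic(Scenario(), nominal_cs)
    assert res.converged
    assert res.periodicity_residual < 1e-6
    assert res.beats_run < 200


def test_kernel_against_solve_ivp_oracle(nominal_cs):
    """Five beats of the RK4 kernel against scipy's LSODA on the same RHS."""
    sc = Scenario(impella_level="P3", ecmo_rpm=1000)
    rhs = assemble_rhs(sc, nominal_cs)
    y0 = initial_state(nominal_cs)
    T = nominal_cs.elastance.period
    sol = solve_ivp(rhs, (0.0, 5 * T), y0, method="LSODA", rtol=1e-10,
                    atol=1e-8, max_step=0.01)
    from mcsloop import _kernel
    from mcsloop.devices import plevel_to_rpm
    pv = pack_parameters(nominal_cs, plevel_to_rpm(sc.impella_level),
                         sc.ecmo_rpm)
    steps = 3200
    act = _kernel.activation_grid(nominal_cs.elastance.t_sys_frac, steps)
    y = y0.copy()
    for _ in range(5):
        _kernel.beat_map(y, pv, act, steps, T / steps)
    assert np.allclose(y, sol.y[:, -1], rtol=0, atol=1e-4 * y.sum())


def test_deterministic_waveforms(nominal_cs):
    a = run_to_periodic(Scenario(ecmo_rpm=2000), nominal_cs)
    b = run_to_periodic(Scenario(ecmo_rpm=2000), nominal_cs)
    assert np.array_equal(a.p_ao, b.p_ao)
    assert np.array_equal(a.v_lv, b.v_lv)


def test_metrics_invariant_to_recorded_beats(nominal_cs):
    from mcsloop import flow_summary, pv_metrics
    r2 = run_to_periodic(Scenario(record_last_beats=2), nominal_cs)
    r4 = run_to_periodic(Scenario(record_last_beats=4), nominal_cs)
    for f2, f4 in ((flow_summary(r2), flow_summary(r4)),):
        assert f2.q_total_mean == pytest.approx(f4.q_total_mean, rel=0.01)
        assert f2.p_ao_mean == pytest.approx(f4.p_ao_mean, rel=0.01)
    assert pv_metrics(r2).sv == pytest.approx(pv_metrics(r4).sv, rel=0.01)


def test_scenario_grid_mirrors_study_conditions():
    grid = scenario_grid()
    assert len(grid) == 33  # 2 baselines + 10 + 6 + 15 (shared cells repeat)
    assert grid[0].condition == "normal" and grid[1].condition == "cs"
    impella_family = grid[2:12]
    assert [s.impella_level for s in impella_family] == [f"P{i}"
                                                         for i in range(10)]
    assert all(s.ecmo_rpm == 0 for s in impella_family)
    ecmo_family = grid[12:18]
    assert [s.ecmo_rpm for s in ecmo_family] == [0, 1000, 1500, 2000, 2500,
                                                 3000]
    combos = {(s.impella_level, s.ecmo_rpm) for s in grid[18:]}
    assert len(grid[18:]) == 15
    assert ("P8", 3000) in combos and ("P0", 0) in combos


def test_scenario_validation():
    with pytest.raises(ValueError):
        Scenario(condition="normal", impella_level="P3")
    with pytest.raises(ValueError):
        Scenario(condition="weird")
    with pytest.raises(KeyError):
        Scenario(impella_level="P11")
    with pytest.raises(ValueError):
        Scenario(ecmo_rpm=-100)
    with pytest.raises(ValueError):
        Scenario(duration_beats=2, record_last_beats=5)


def test_parameter_file_round_trip(tmp_path, nominal_cs):
    path = tmp_path / "params.yaml"
    save_parameters(nominal_cs, path)
    lp = load_parameters(path)
    assert lp.circuit == nominal_cs.circuit
    assert lp.elastance == nominal_cs.elastance
    assert lp.impella == nominal_cs.impella
    assert lp.ecmo == nominal_cs.ecmo


def test_inertance_not_supported(nominal_cs):
    lp = dataclasses.replace(
        nominal_cs, circuit=dataclasses.replace(nominal_cs.circuit,
                                                l_aortic=0.001))
    with pytest.raises(NotImplementedError):
        pack_parameters(lp)
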