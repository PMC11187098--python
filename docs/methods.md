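# Model and methods

`mcsloop` is a lumped-parameter (0D) digital twin of a pulsatile mock
circulatory loop built to study mechanical circulatory support in
cardiogenic shock: a pneumatically driven silicone ventricle ejecting
through an aortic valve into a silicone aortic arch with a brachiocephalic
branch, a descending segment to the iliac arteries, a clamp-set peripheral
resistance, and an open venous reservoir feeding the mitral valve.  An
Impella CP (transvalvular axial pump, levels P0–P9 / 0–46,000 rpm) pumps
from the ventricle into the ascending aorta; a VA-ECMO circuit drains the
venous reservoir and returns blood retrogradely at the left iliac artery.
Heart rate is fixed at 75 beats/min.

## Network and constitutive laws

State vector: the volumes of four compartments — left ventricle, aortic
arch, distal artery (iliac junction), venous reservoir.  All units are
mmHg, ml, s; flows are converted to L/min only at the I/O boundary.

- **Ventricle** — time-varying elastance `P = E(t)(V − V0)` with a
  normalized double-Hill activation (exponents 1.9 / 21.9, timescales tied
  to the systolic fraction `t_sys_frac`) between `e_min` and `e_max`.  The
  pneumatic console of the physical rig is not modelled as an air circuit;
  its drive settings are absorbed into the calibrated elastances.
  Cardiogenic shock = lower `e_max` (contractility) with the vascular side
  unchanged; preload rises through the circulating-volume/MCFP setting.
- **Valves** — one-way resistances with a C1 piecewise-quadratic diode
  transition (half-width `smoothing`, default 0.3 mmHg).  Exactly zero flow
  against the gradient: no regurgitation and no leak at zero gradient, so
  the loop relaxes exactly to the mean circulatory filling pressure (MCFP)
  when the drive is off.
- **Aortic arch** — nonlinear stiffness-law compliance.  The vessel
  stiffness parameter β (= 6.0, matched to porcine aorta in the bench rig)
  defines `ln(P/Ps) = β(D/Ds − 1)`; treating the arch as a constant-length
  tube (`D ∝ √V`) gives the volume law `ln(P/Ps) = β(√(V/Vs) − 1)` with
  `Ps = 100 mmHg` (the conventional reference) and `Vs` a calibrated
  reference volume.
- **Distal artery** — small linear compliance (0.3 ml/mmHg, fixed): the
  junction node where the descending aorta, ECMO return and peripheral
  runoff meet.  It makes every branch flow an explicit function of state.
- **Venous reservoir** — linear compliance `c_venous` above an unstressed
  volume.  The physical reservoir is an open tank, so `c_venous` is an
  effective free-surface compliance.
- **Clamped branches** — the bench sets peripheral and brachiocephalic
  resistance with tube clamps, which behave like orifices; both branches
  therefore carry `ΔP = R q + k q|q|` with quadratic coefficients
  `k_systemic`, `k_brachio` (default 0).  The purely linear network cannot
  reconcile the two printed baselines (normal: ~4.9 L/min at ~80 mmHg
  perfusion pressure; shock: ~3.2 L/min at ~41 mmHg) under the shared-clamp
  constraint; the orifice term does.
- **Pumps** — minimal rotodynamic characteristic
  `c_speed ω² − c_flow q² − r q = ΔP`, solved for `q ≥ 0` (no backflow;
  inert at zero speed, so P0 and 0 rpm reproduce the unsupported baseline
  exactly).  The Impella head is `p_ao − p_lv`; the ECMO head is the
  distal-arterial minus venous pressure with the whole circuit lumped into
  `r_circuit`.  A suction guard linearly derates Impella flow as LV
  pressure falls from +2 mmHg to −5 mmHg, mimicking inlet suction against
  an under-filled ventricle.
- **Aortic inertance** — not integrated.  The printed pulse pressures are
  attainable without it, so `l_aortic` must be 0 (the field is retained on
  the parameter container).

Volume is conserved exactly by construction: the four compartment
derivatives sum to zero at every instant, and the fixed-step integrator
preserves the sum to round-off.

## Integration and periodic steady state

The beat is integrated with fixed-step RK4 (3,200 steps/beat, dt = 0.25 ms)
in a numba-compiled kernel; the activation waveform is pre-tabulated on the
half-step grid.  The slowest mode of the loop — venous volume
redistribution — has a time constant of order 100 s (hundreds of beats), so
plain beat-to-beat iteration is impractical inside an optimizer.  Instead
the periodic orbit is found by Newton iteration on the stroboscopic
(one-beat) map in reduced coordinates (three free volumes; the fourth is
fixed by conservation), with finite-difference Jacobians and plain
iteration as a fallback.  Typical convergence: 10–20 beats of work to an
end-of-beat defect below 1e−9 (relative), which makes the calibration
objective smooth and history-independent.  A recorded run reports the
consecutive-beat trajectory residual alongside the waveforms (800
samples/beat over the recorded beats).

The simulator is also the package's synthetic-data generator: analysis and
calibration are tested against its pulsatile waveforms.  It emulates
waveform shape, device interactions and the probe bookkeeping of the bench
(descending-aortic probe between the brachiocephalic branch and the ECMO
return; total flow = iliac + brachiocephalic).  It does not emulate
measurement noise, beat-to-beat variability, valve regurgitation, wave
propagation, or the right heart — agreement of tests on model-generated
data therefore demonstrates internal consistency of the pipeline, not
fidelity to any particular animal or patient.

## Analysis conventions

End-diastole is the maximum-volume instant of a beat, end-systole the
minimum-volume instant; `SV = EDV − ESV` holds by construction.  Pressure
summaries are per-beat max / per-beat min averaged over recorded beats plus
the time mean ("sys/dia (mean)").  `Ees` is model-based — the line through
the end-systolic point and `(V0, 0)` — because per-scenario preload
variation is not simulated; `Ea = ESP/SV`; `PVA` is the loop (shoelace)
area plus the end-systolic triangle `½·ESP·(ESV − V0)`.  The
brachiocephalic share of output uses aortic-probe + brachiocephalic flow as
the denominator, which reproduces the printed 12.2% / 12.5% shares.  The
aortic flow-direction class uses a ±0.15 L/min stagnation band, chosen so
the printed watershed values (−0.05, −0.10, +0.07 L/min) classify as
stagnant and −0.27 as retrograde; the band is a configurable argument.

## Calibration protocol

Printed bench measurements (packaged as CSV fixtures, transcribed verbatim,
anomalies flagged but never altered) are split once: the two device-free
baselines plus the two single-device dose-response tables are training
data; the fifteen combination conditions are hold-out and are never seen by
any fit.

**Stage 1** fits 13 parameters (clamp coefficients, segment and valve
resistances, arterial reference volume, venous compliance, two `e_max`
values, `e_min`, `V0`, systolic fraction) to the 22 baseline records, with
the MCFP pinned exactly at 7 mmHg (normal) / 13 mmHg (shock) by solving the
circulating volume analytically at every step.  Residuals are relative
errors; the four headline anchors (mean aortic pressure and mean
aortic-probe flow, both conditions) carry weight 3 because the bench's own
sessions disagree at the 10–25% level and those anchors define the
conditions.  Bounded trust-region least squares, three deterministic
starts.

**Stage 2** freezes the baseline and fits the six pump coefficients
*jointly with the venous compliance* to the hydraulic records of the two
dose-response tables (total flow, aortic sys/dia/mean, venous reservoir
pressure; PV-catheter quantities are excluded — pump hydraulics should be
identified by hydraulic measurements, and the conductance-derived volumes
carry a session offset the three pump coefficients cannot absorb).
`c_venous` belongs to this stage because the baseline records cannot
identify it: both printed baseline venous pressures sit at or above the
MCFP, which is outside the reachable set of any closed-loop model with
monotone pressure–volume laws, whereas the venous-unloading dose responses
(15.0 → 9.1 and 15.0 → 7.0 mmHg) are exactly the measurements that
exercise it.  The endpoint rows each table is quoted by (P9; 3000 rpm)
carry weight 3, the published 3.7 L/min mean-flow capability of the
Impella CP enters as a one-sided penalty, and the Impella `c_speed` bounds
keep the shut-off head at P9 near the device's published ~100 mmHg order —
the training tables only exercise afterloads of 46–76 mmHg, so the head
margin at combination afterloads is otherwise unidentified.  Log-scale
parameters, five deterministic starts.

**Hold-out prediction** simulates the 5 × 3 combination grid with frozen
parameters and reports per-record errors and flow-direction classes.

Everything is deterministic: no stochastic optimizer, no random seeds in
the model; repeated runs are bit-identical.

## Known limitations

- The bench data are internally inconsistent across measurement sessions
  (baseline aortic pressure 54 vs 46 mmHg; conductance-catheter stroke
  volumes exceed flow-probe totals by up to 40%; baseline venous pressures
  above the MCFP; Table 4's 3000-rpm mass balance implies cardiac output
  below brachiocephalic flow).  A mass-conserving model cannot match all of
  these simultaneously; the calibration design above chooses which records
  anchor the fit and the residual tables expose the rest.
- The final shock model is the stage-2 parameter set; its unsupported
  baseline settles near the table-session baseline (~47 mmHg mean aortic
  pressure) rather than the waveform-session one (54 mmHg).
- Combination totals are over-predicted by ~10–15%: the training data
  imply more flow at high perfusion pressure than the combination tables
  record (the same session inconsistency seen from the other side).
- The 13-parameter vasculature/ventricle fit is sloppy in the usual 0D
  sense: with only two baseline operating points, several directions
  (e.g. aortic-segment resistance vs arterial volume scale, systolic
  fraction vs elastances, pump quadratic-loss vs linear-loss splits) are
  compensated to within <0.1% data error, so individual parameters in
  those directions are not recoverable even from exact model-generated
  data; predictions, not raw parameter values, are the validated output.
- Right heart, pulmonary circulation, gas exchange, hemolysis and thrombus
  mechanics are out of scope; flow-direction classification is the only
  stagnation-related output.
- `v_total` is the model's *effective* circulating volume above lumped
  unstressed volumes and is smaller than the physical rig's ~5,500 ml
  capacity; conduit dead volumes are unobservable and folded into the
  unstressed terms.
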