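"""Run the full two-stage calibration and the hold-out validation.

Stage 1 fits the vascular bed and ventricle to the two device-free baseline
measurements (under hard 7 / 13 mmHg filling-pressure constraints); stage 2
fits the two pump characteristics plus the venous compliance to the
single-device dose-response tables.  The fifteen Impella + VA-ECMO
combination conditions are then simulated with frozen parameters and
compared against the printed combination tables — a genuine prediction,
since no fit ever saw those records.

Takes a couple of minutes; prints the per-stage costs (root of twice the
cost is roughly the rms relative misfit) and the hold-out error summary.
"""

from mcsloop import predict_holdout, run_full_calibration

model = run_full_calibration()
print(f"stage-1 cost {model.baseline_fit.cost:.4f} "
      f"(multistart: {[round(c, 3) for c in model.baseline_fit.multistart_costs]})")
print(f"stage-2 cost {model.pump_fit.cost:.4f}")
print("fitted pump parameters:")
for k, v in model.pump_fit.parameters.items():
    print(f"  {k:20s} {v:.4g}")

pred = predict_holdout(model)
hold = pred[pred.is_holdout]
print(f"\nhold-out records: {len(hold)}")
for q in ("total_flow", "p_ao_mean", "p_vr_mean", "q_aorta"):
    sub = hold[hold.quantity == q]
    if len(sub):
        mae = sub.abs_error.abs().mean()
        print(f"  {q:12s} mean |error| {mae:6.2f}  "
              f"(reference range {sub.reference.min():.2f}"
              f"..{sub.reference.max():.2f})")
top = pred[(pred.impella_level == "P8") & (pred.ecmo_rpm == 3000)]
total = top[top.quantity == "total_flow"]
print(f"\nmaximum support (P8 + 3000 rpm): predicted total "
      f"{float(total.predicted.iloc[0]):.2f} L/min vs printed "
      f"{float(total.reference.iloc[0]):.2f}")
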