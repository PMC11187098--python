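"""Simulate the two device-free conditions of the mock loop and print their
hemodynamics and pressure-volume loop indices.

The normal condition is filled to a mean circulatory filling pressure of
7 mmHg with full contractility; cardiogenic shock keeps the same vascular
bed but drops the end-systolic elastance and raises the fill to 13 mmHg.
Expect the shock run to show a mean aortic pressure in the high 40s vs
~88 mmHg for normal, a smaller stroke volume on a rightward-shifted loop,
and a higher venous reservoir pressure — the signature of a failing,
volume-loaded ventricle.
"""

from importlib import resources

from mcsloop import Scenario, flow_summary, load_parameters, pv_metrics, \
    run_to_periodic


def packaged(condition):
    with resources.as_file(resources.files("mcsloop.data")
                           / f"params_{condition}.yaml") as p:
        return load_parameters(p)


for condition in ("normal", "cs"):
    lp = packaged(condition)
    res = run_to_periodic(Scenario(condition=condition), lp)
    hs = flow_summary(res)
    pm = pv_metrics(res)
    print(f"\n== {condition} (converged in {res.beats_run} beats) ==")
    print(f"  aortic pressure   {hs.p_ao_sys:5.0f}/{hs.p_ao_dia:.0f} "
          f"({hs.p_ao_mean:.0f}) mmHg")
    print(f"  aortic flow       {hs.q_aorta_mean:5.2f} L/min "
          f"(+ {hs.q_brachio_mean:.2f} brachiocephalic, "
          f"{hs.brachio_fraction:.1f}% of output)")
    print(f"  venous reservoir  {hs.p_vr_mean:5.1f} mmHg")
    print(f"  P-V loop: peak {pm.peak_vp:.0f} mmHg, EDP {pm.edp:.0f} mmHg, "
          f"EDV {pm.edv:.0f} ml, ESV {pm.esv:.0f} ml, SV {pm.sv:.0f} ml")
    print(f"  Ees {pm.ees:.2f} mmHg/ml, Ea {pm.ea:.2f} mmHg/ml, "
          f"PVA {pm.pva:.0f} mmHg*ml")
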