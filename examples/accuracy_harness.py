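"""Run the built-in curve-accuracy harness and show it catching a bad engine.

Each built-in case is checked in three categories: SE (start/end anchors),
Ip (interior and interpolated points) and Rg (x/y ranges).  Every expected
value is derived by brute-force oracles, never hand-entered.  A deliberately
simplified engine that connects PR points with straight chords passes SE and
Rg but fails Ip — exactly the failure mode the harness exists to detect.
"""

from precurve.testkit import linear_interpolation_engine, run_accuracy_suite

print("shipped engine:")
report = run_accuracy_suite()
for case_id, cats in report.per_case.items():
    print(f"  {case_id}: " + ", ".join(f"{c} {s}/{t}" for c, (s, t) in cats.items()))
print(f"  overall: {'PASS' if report.overall_pass else 'FAIL'}\n")

print("linear-interpolation engine (deliberately wrong for PR):")
broken = run_accuracy_suite(engine=linear_interpolation_engine)
for case_id, cats in broken.per_case.items():
    print(f"  {case_id}: " + ", ".join(f"{c} {s}/{t}" for c, (s, t) in cats.items()))
print(f"  overall: {'PASS' if broken.overall_pass else 'FAIL'}")
for f in broken.failures:
    print(f"  failed {f['case']} {f['curve_type']} {f['category']} at x={f.get('x')}: {f['detail']}")
# The same command is available from the shell as `precurve selftest`.
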