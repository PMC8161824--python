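"""Probabilistic sensitivity analysis of the reference case.

Each iteration samples every parameter from its uncertainty
distribution (gamma costs, beta utilities/probabilities, per-cycle beta
draws of the transition schedules), runs both arms on the shared draw,
and records discounted cost and QALYs.  The ICER is the ratio of mean
increments; the CEAC gives the probability SABR is cost-effective at
each willingness-to-pay threshold.
"""
from oligocea import ceac, make_reference_config, run_reference_case

config, curves = make_reference_config()
report = run_reference_case(config, curves, n_iter=2000, seed=42)

s = report["summary"]
print(f"{'':14s}{'cost (95% CI)':>38s}{'QALYs (95% CI)':>28s}")
for arm in ("SABR", "SoC"):
    c, q = s[arm]["cost"], s[arm]["qaly"]
    print(f"{arm:14s}CAD {c['mean']:>10,.0f} ({c['ci_low']:,.0f}-{c['ci_high']:,.0f})"
          f"{q['mean']:>12.2f} ({q['ci_low']:.2f}-{q['ci_high']:.2f})")
inc = s["incremental"]
print(f"\nincremental cost CAD {inc['cost']['mean']:,.0f}, "
      f"incremental QALYs {inc['qaly']['mean']:.2f}")
print(f"ICER: {report['icer_display']} per QALY gained")

curve = report["ceac"]
for wtp in (50_000, 100_000):
    print(f"P(cost-effective at CAD {wtp:,}/QALY) = {curve.at(wtp):.0%}")

# These are synthetic reference outputs: the trial curves behind them
# are generated, not digitized from the published figures.
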