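"""Run one arm of the Markov cohort model at point estimates.

The SABR arm starts in a single-cycle treatment state (carrying the
time-zero cost), then moves through Stable Disease, Progression and
Supportive Care toward Death.  Death probabilities per cycle come from
the fitted OS curve, progression from the PFS-minus-OS hazard split.
"""
from oligocea import (
    accumulate,
    assemble_transitions,
    build_arm_schedules,
    make_reference_config,
    run_cohort,
)

config, curves = make_reference_config()
schedules = build_arm_schedules(config, curves, horizon=5.0)

arm = config.intervention
trans = assemble_transitions(arm, schedules["intervention"]["os"],
                             schedules["intervention"]["pfs"])
trace = run_cohort(trans, arm.initial_state, 20, cycle_length=3.0)
print("cohort occupancy (every 4th cycle):")
print(trace.to_frame().iloc[::4].round(3).to_string(index=False))

res = accumulate(trace, arm.states, config.settings.discount_rate, transitions=trans)
print(f"\ndiscounted (1.5%/yr): cost CAD {res.total_cost:,.0f}, "
      f"QALYs {res.total_qaly:.2f}, life-years {res.total_ly:.2f}")
print(f"undiscounted:        cost CAD {res.undiscounted_cost:,.0f}, "
      f"QALYs {res.undiscounted_qaly:.2f}")

# The treatment state empties after cycle 0 (one course of SABR); the
# absorbing Death column grows monotonically.
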