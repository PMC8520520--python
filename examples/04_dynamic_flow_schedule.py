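"""Derive the dynamic flow-rate protocol that holds cell shear constant.

Computes the early-stage target (small-cell peak shear at the
polarization-initiating wall shear of 0.02 dyn/cm2), then schedules the
flow over a morphology timeline in which the monolayer turns tall at day 5.
Each sensitivity is one or two flow solves, so this takes about a minute.
"""

from gutchip import (
    MorphologyTimeline,
    early_stage_target,
    schedule_flow,
    standard_protocols,
)

target = early_stage_target()
print(f"early-stage cell-shear target: {target:.4f} dyn/cm2")

timeline = MorphologyTimeline(entries=((2, "small"), (5, "tall")), end_day=8)
schedule = schedule_flow(timeline, target)
print(schedule.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("Holding the early-stage cell shear while the monolayer polarizes")
print("steps the pump from ~29 uL/hr down to ~18 uL/hr at day 5 — the")
print("dynamic-flow protocol.  For reference, the three benchmark")
print("conditions are:")
for name, prot in standard_protocols().items():
    steps = ", ".join(
        f"{iv.q_ul_hr:g} uL/hr on [{iv.day_start},{iv.day_end})" for iv in prot.intervals
    )
    print(f"  {name}: {steps}")
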