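"""Flow-rate schedules that hold the *cell* shear stress constant.

The usual perfusion-culture practice fixes the wall shear stress τw (hence
the flow rate) for the whole experiment.  But as epithelial cells polarize
they grow from low bulges into tall columns, and the shear stress on the
cell surface τc rises even at constant τw.  Because the flow is creeping
(Re ≪ 1), τc is exactly proportional to the flow rate for a fixed
morphology, so a per-morphology sensitivity k = τc/Q turns "hold τc at a
target" into a stepwise schedule: on each interval of a morphology
timeline, Q = τc_target / k(morphology).

The default target is the early-stage value: the peak τc of a small
bulge-shaped cell at the polarization-initiating wall shear of
0.02 dyn/cm².  With the default morphologies this schedule starts at
≈ 29 µL/hr and steps down to ≈ 18 µL/hr once the monolayer is tall —
the dynamic-flow protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .geometry import (
    CellArraySpec,
    CellMorphology,
    build_domain,
    cell_array,
    morphology_defaults,
)
from .hydraulics import (
    ChannelSpec,
    FluidProperties,
    culture_medium,
    fabricated_channel,
    flow_rate_for_wall_shear,
)
from .shear import cell_shear_summary
from .solver import SolverConfig, solve_flow

#: Default arrangement per morphology: early-stage small cells are
#: subconfluent (single bulge, the bulge-model setting); by the time the
#: monolayer is medium/tall it is confluent, so the array's outer cell sets
#: the exposure.
DEFAULT_ARRANGEMENTS: dict[str, int] = {"small": 1, "medium": 5, "tall": 5}

POLARIZATION_WALL_SHEAR = 0.02  # dyn/cm², the literature's initiation value


class SchedulingError(ValueError):
    """A schedule cannot be realized (e.g. pump limit exceeded)."""


@dataclass(frozen=True)
class MorphologyTimeline:
    """Ordered (day, morphology label) checkpoints plus an end day.

    Each label applies from its day (inclusive) to the next entry's day
    (exclusive); the last label runs to ``end_day``.
    """

    entries: tuple[tuple[int, str], ...]
    end_day: int

    def __post_init__(self) -> None:
        if not self.entries:
            raise SchedulingError("timeline must contain at least one entry")
        days = [d for d, _ in self.entries]
        if any(d < 0 for d in days):
            raise SchedulingError("days must be >= 0")
        if any(a >= b for a, b in zip(days, days[1:])):
            raise SchedulingError("days must be strictly increasing")
        if self.end_day <= days[-1]:
            raise SchedulingError("end_day must exceed the last entry's day")
        for _, label in self.entries:
            morphology_defaults(label)  # raises on unknown labels

    def intervals(self) -> list[tuple[int, int, str]]:
        """Half-open (start, end, label) intervals partitioning the span."""
        out = []
        for k, (day, label) in enumerate(self.entries):
            end = self.entries[k + 1][0] if k + 1 < len(self.entries) else self.end_day
            out.append((day, end, label))
        return out


@dataclass(frozen=True)
class ScheduleInterval:
    day_start: int
    day_end: int
    q_ul_hr: float
    predicted_tau_c: float | None

    @property
    def q_display(self) -> float:
        """Flow rate rounded to the nearest 1 µL/hr (pump setting)."""
        return round(self.q_ul_hr)


@dataclass(frozen=True)
class FlowSchedule:
    """Stepwise-constant flow schedule over an experiment span."""

    intervals: tuple[ScheduleInterval, ...]
    tau_c_target: float | None = None
    name: str = ""

    def q_at(self, day: float) -> float:
        for iv in self.intervals:
            if iv.day_start <= day < iv.day_end:
                return iv.q_ul_hr
        if self.intervals and day == self.intervals[-1].day_end:
            return self.intervals[-1].q_ul_hr
        raise SchedulingError(f"day {day} outside the scheduled span")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "day_start": iv.day_start,
                    "day_end": iv.day_end,
                    "Q_uL_hr": iv.q_display,
                    "Q_uL_hr_exact": iv.q_ul_hr,
                    "predicted_tau_c": iv.predicted_tau_c,
                }
                for iv in self.intervals
            ]
        )


@dataclass(frozen=True)
class ShearSensitivity:
    """Cell shear stress per unit flow rate for one morphology/arrangement."""

    label: str
    k: float  # dyn/cm² per µL/hr
    reference_q_ul_hr: float
    linear: bool
    arrangement: str


def _solve_peak(
    morphology: CellMorphology,
    array: CellArraySpec,
    q_ul_hr: float,
    channel: ChannelSpec,
    fluid: FluidProperties,
    config: SolverConfig,
) -> float:
    from dataclasses import replace

    from .shear import geometry_spacing_um

    # refine spacing where the arrangement's gaps demand it (>= 8 cells per
    # smallest geometric feature)
    spacing = geometry_spacing_um(morphology, array, channel, config.grid_spacing_um)
    cfg = replace(config, grid_spacing_um=spacing)
    dom = build_domain(channel, array, morphology, resolution_um=spacing)
    fld = solve_flow(dom, q_ul_hr, fluid, cfg)
    return cell_shear_summary(fld, dom, fluid).tau_c_peak


def shear_sensitivity(
    morphology: CellMorphology | str,
    channel: ChannelSpec | None = None,
    fluid: FluidProperties | None = None,
    config: SolverConfig | None = None,
    arrangement: CellArraySpec | None = None,
    reference_q_ul_hr: float = 29.0,
    verify_linearity: bool = True,
    linearity_rtol: float = 0.01,
) -> ShearSensitivity:
    """Peak cell shear per unit flow rate, k = τc_peak/Q (dyn/cm² per µL/hr).

    One solve at the reference flow rate fixes k; when
    ``verify_linearity`` a second solve at 2Q must reproduce k within
    ``linearity_rtol`` (automatic in the Stokes regime; in
    ``navier_stokes`` mode a failure downgrades the result to
    ``linear=False`` with a warning, and the scheduler then refines each
    interval with a direct solve).
    """
    if isinstance(morphology, str):
        morphology = morphology_defaults(morphology)
    channel = channel or fabricated_channel()
    fluid = fluid or culture_medium()
    config = config or SolverConfig()
    if arrangement is None:
        arrangement = cell_array(DEFAULT_ARRANGEMENTS.get(morphology.label, 1))
    tau1 = _solve_peak(morphology, arrangement, reference_q_ul_hr, channel, fluid, config)
    k = tau1 / reference_q_ul_hr
    linear = True
    if verify_linearity:
        tau2 = _solve_peak(
            morphology, arrangement, 2.0 * reference_q_ul_hr, channel, fluid, config
        )
        if abs(tau2 / 2.0 - tau1) / tau1 > linearity_rtol:
            linear = False
            warnings.warn(
                f"shear response of {morphology.label!r} deviates from "
                f"linearity by more than {linearity_rtol:.0%}; scheduler will "
                "solve each interval directly",
                stacklevel=2,
            )
    return ShearSensitivity(
        label=morphology.label,
        k=k,
        reference_q_ul_hr=reference_q_ul_hr,
        linear=linear,
        arrangement=arrangement.arrangement,
    )


def early_stage_target(
    channel: ChannelSpec | None = None,
    fluid: FluidProperties | None = None,
    config: SolverConfig | None = None,
) -> float:
    """Default τc target: small-cell peak shear at τw = 0.02 dyn/cm².

    The polarization-initiating condition is the flow rate whose
    parallel-plate wall shear is 0.02 dyn/cm² (≈ 29 µL/hr in the fabricated
    chip); the target is the peak shear a small bulge-shaped cell
    experiences there.
    """
    channel = channel or fabricated_channel()
    fluid = fluid or culture_medium()
    q0 = flow_rate_for_wall_shear(POLARIZATION_WALL_SHEAR, channel, fluid)
    sens = shear_sensitivity(
        "small", channel, fluid, config, reference_q_ul_hr=q0, verify_linearity=False
    )
    return sens.k * q0


def schedule_flow(
    timeline: MorphologyTimeline,
    tau_c_target: float,
    channel: ChannelSpec | None = None,
    fluid: FluidProperties | None = None,
    config: SolverConfig | None = None,
    pump_max_ul_hr: float | None = None,
    sensitivities: Mapping[str, ShearSensitivity] | None = None,
) -> FlowSchedule:
    """Stepwise flow schedule holding τc at ``tau_c_target`` over a timeline.

    Per interval, Q = target / k(morphology); sensitivities are computed
    once per distinct label (or supplied precomputed via
    ``sensitivities``).  Raises :class:`SchedulingError` if any interval
    requires more than ``pump_max_ul_hr``.
    """
    if tau_c_target < 0.0:
        raise SchedulingError(f"target must be >= 0, got {tau_c_target}")
    if tau_c_target == 0.0:
        warnings.warn("zero shear target: schedule degenerates to no flow", stacklevel=2)
    channel = channel or fabricated_channel()
    fluid = fluid or culture_medium()
    cache: dict[str, ShearSensitivity] = dict(sensitivities or {})
    intervals = []
    for start, end, label in timeline.intervals():
        if tau_c_target == 0.0:
            intervals.append(ScheduleInterval(start, end, 0.0, 0.0))
            continue
        if label not in cache:
            cache[label] = shear_sensitivity(label, channel, fluid, config)
        sens = cache[label]
        q = tau_c_target / sens.k
        if not sens.linear:
            morph = morphology_defaults(label)
            arr = cell_array(DEFAULT_ARRANGEMENTS.get(label, 1))
            tau = _solve_peak(morph, arr, q, channel, fluid, config or SolverConfig())
            q *= tau_c_target / tau
        if pump_max_ul_hr is not None and q > pump_max_ul_hr:
            raise SchedulingError(
                f"interval [{start}, {end}) needs {q:.1f} µL/hr, above the "
                f"pump maximum {pump_max_ul_hr} µL/hr"
            )
        intervals.append(ScheduleInterval(start, end, q, sens.k * q))
    return FlowSchedule(tuple(intervals), tau_c_target=tau_c_target, name="dynamic")


def standard_protocols(day_start: int = 2, day_mid: int = 5, day_end: int = 8) -> dict[str, FlowSchedule]:
    """The three benchmark perfusion conditions over days 2–8.

    ``C``: constant 29 µL/hr; ``D``: 29 µL/hr, decreased to 18 µL/hr from
    ``day_mid``; ``S``: static culture (no flow, daily media change).
    """
    c = FlowSchedule(
        (ScheduleInterval(day_start, day_end, 29.0, None),), name="C"
    )
    d = FlowSchedule(
        (
            ScheduleInterval(day_start, day_mid, 29.0, None),
            ScheduleInterval(day_mid, day_end, 18.0, None),
        ),
        name="D",
    )
    s = FlowSchedule((ScheduleInterval(day_start, day_end, 0.0, None),), name="S")
    return {"C": c, "D": d, "S": s}
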