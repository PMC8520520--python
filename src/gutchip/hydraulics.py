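"""Fluid/channel data types and closed-form hydraulic relations.

The microchannel is a shallow rectangle (width w ≫ height h), so the
parallel-plate flow-chamber model applies: for steady laminar flow of a
Newtonian medium at volumetric rate Q, the shear stress on the wide walls is

    τw = 6 µ Q / (w h²)

which inverts to the flow rate that delivers a prescribed wall shear,
Q = τw w h² / (6 µ).  Cells attached to the floor protrude into the moving
fluid and experience more than τw; the classical bulge model (adherent cell
approximated as a low hemispherical bump) predicts a peak cell shear stress
of τc ≈ 3 τw.  Everything here is closed form; the flow solver in
:mod:`gutchip.solver` provides the numerical counterpart for cells whose
shape has outgrown the bulge approximation.

Internal unit system is CGS (cm, g, s, dyn); constructors and helpers accept
the mixed units common in the literature (µL/hr, µm, N·s/cm²) explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from . import units


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible domain."""


@dataclass(frozen=True)
class FluidProperties:
    """Constant density and dynamic viscosity of the perfusion medium.

    Attributes
    ----------
    density
        Mass density ρ in g/cm³.
    dynamic_viscosity
        Shear viscosity µ in dyn·s/cm² (poise).
    """

    density: float = 1.0
    dynamic_viscosity: float = 9.3e-3

    def __post_init__(self) -> None:
        if not (self.density > 0.0):
            raise InvalidParameterError(f"density must be > 0, got {self.density}")
        if not (self.dynamic_viscosity > 0.0):
            raise InvalidParameterError(
                f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}"
            )

    @classmethod
    def from_viscosity(
        cls, value: float, viscosity_units: str, density: float = 1.0
    ) -> "FluidProperties":
        """Build from a viscosity quoted in any supported unit.

        ``FluidProperties.from_viscosity(9.3e-8, "N.s/cm2")`` stores
        µ = 9.3e-3 dyn·s/cm² (0.93 cP, plausible for DMEM + 10% FBS at 37 °C).
        """
        return cls(density=density, dynamic_viscosity=units.viscosity_to_cgs(value, viscosity_units))


def culture_medium() -> FluidProperties:
    """DMEM + 10% serum at 37 °C: ρ = 1 g/cm³, µ = 9.3×10⁻⁸ N·s/cm²."""
    return FluidProperties.from_viscosity(9.3e-8, "N.s/cm2", density=1.0)


@dataclass(frozen=True)
class ChannelSpec:
    """Rectangular microchannel: width w, height h, length L, all in cm.

    The parallel-plate relation assumes w ≫ h; a channel with w < h is
    accepted with a warning because the formula degrades rather than fails.
    """

    width: float
    height: float
    length: float

    def __post_init__(self) -> None:
        for name in ("width", "height", "length"):
            if not (getattr(self, name) > 0.0):
                raise InvalidParameterError(
                    f"channel {name} must be > 0, got {getattr(self, name)}"
                )
        if self.width < self.height:
            warnings.warn(
                "channel width < height: the parallel-plate (wide channel) "
                "assumption behind the wall-shear formula is violated",
                stacklevel=2,
            )

    @property
    def aspect_ratio(self) -> float:
        """Width-to-height ratio w/h."""
        return self.width / self.height

    @property
    def cross_section_area(self) -> float:
        """Cross-section area w·h in cm²."""
        return self.width * self.height


def fabricated_channel() -> ChannelSpec:
    """The fabricated chip channel: w = 0.1 cm, h = 0.015 cm, L = 1.2 cm."""
    return ChannelSpec(width=0.1, height=0.015, length=1.2)


def wall_shear_stress(
    q_ul_hr: float, channel: ChannelSpec, fluid: FluidProperties
) -> float:
    """Wall shear stress τw = 6µQ/(wh²) in dyn/cm² for Q in µL/hr.

    This is the parallel-plate reference value used throughout the package
    as the denominator of cell-shear amplification ratios.
    """
    if q_ul_hr < 0.0:
        raise InvalidParameterError(f"flow rate must be >= 0, got {q_ul_hr}")
    q = units.ul_per_hr_to_cm3_s(q_ul_hr)
    return 6.0 * fluid.dynamic_viscosity * q / (channel.width * channel.height**2)


def flow_rate_for_wall_shear(
    tau_w: float, channel: ChannelSpec, fluid: FluidProperties
) -> float:
    """Flow rate (µL/hr) producing wall shear τw (dyn/cm²); inverse of
    :func:`wall_shear_stress` to machine precision."""
    if tau_w < 0.0:
        raise InvalidParameterError(f"wall shear must be >= 0, got {tau_w}")
    q = tau_w * channel.width * channel.height**2 / (6.0 * fluid.dynamic_viscosity)
    return units.cm3_s_to_ul_per_hr(q)


def bulge_model_cell_shear(tau_w: float) -> float:
    """Peak cell shear stress under the bulge model: τc = 3 τw.

    Valid for low, approximately hemispherical adherent cells; tall columnar
    cells exceed this (see :mod:`gutchip.shear`).
    """
    if tau_w < 0.0:
        raise InvalidParameterError(f"wall shear must be >= 0, got {tau_w}")
    return 3.0 * tau_w


def inlet_velocity_profile(
    z_cm: float, q_ul_hr: float, channel: ChannelSpec
) -> float:
    """Fully developed plane-Poiseuille streamwise velocity u(z) in cm/s.

    u(z) = 6 (Q/(w h)) (z/h)(1 − z/h): zero at both walls, peak 1.5× the
    mean velocity at mid-height, and integrates over the cross section to Q.
    """
    h = channel.height
    if not (0.0 <= z_cm <= h):
        raise InvalidParameterError(f"z = {z_cm} outside channel [0, {h}]")
    if q_ul_hr < 0.0:
        raise InvalidParameterError(f"flow rate must be >= 0, got {q_ul_hr}")
    q = units.ul_per_hr_to_cm3_s(q_ul_hr)
    mean_u = q / channel.cross_section_area
    zeta = z_cm / h
    return 6.0 * mean_u * zeta * (1.0 - zeta)


def reynolds_number(
    q_ul_hr: float, channel: ChannelSpec, fluid: FluidProperties
) -> float:
    """Channel Reynolds number Re = ρ U h / µ with U = Q/(wh).

    At the perfusion rates used for epithelial culture Re ≪ 1, which is why
    the creeping-flow (Stokes) regime is the solver default.
    """
    if q_ul_hr < 0.0:
        raise InvalidParameterError(f"flow rate must be >= 0, got {q_ul_hr}")
    q = units.ul_per_hr_to_cm3_s(q_ul_hr)
    mean_u = q / channel.cross_section_area
    return fluid.density * mean_u * channel.height / fluid.dynamic_viscosity


@dataclass(frozen=True)
class FlowCondition:
    """A volumetric flow rate together with its parallel-plate wall shear.

    ``tau_w`` is derived and cached at construction; the two fields stay
    consistent through the parallel-plate relation by construction.
    """

    q_ul_hr: float
    tau_w: float = field(default=float("nan"))
    channel: ChannelSpec = field(default_factory=fabricated_channel)
    fluid: FluidProperties = field(default_factory=culture_medium)

    def __post_init__(self) -> None:
        if self.q_ul_hr < 0.0:
            raise InvalidParameterError(f"flow rate must be >= 0, got {self.q_ul_hr}")
        expected = wall_shear_stress(self.q_ul_hr, self.channel, self.fluid)
        if math.isnan(self.tau_w):
            object.__setattr__(self, "tau_w", expected)
        else:
            scale = max(abs(expected), 1e-300)
            if abs(self.tau_w - expected) / scale > 1e-9:
                raise InvalidParameterError(
                    f"tau_w = {self.tau_w} inconsistent with Q = {self.q_ul_hr} µL/hr "
                    f"(parallel-plate value {expected})"
                )

    @classmethod
    def from_wall_shear(
        cls,
        tau_w: float,
        channel: ChannelSpec | None = None,
        fluid: FluidProperties | None = None,
    ) -> "FlowCondition":
        channel = channel or fabricated_channel()
        fluid = fluid or culture_medium()
        q = flow_rate_for_wall_shear(tau_w, channel, fluid)
        return cls(q_ul_hr=q, channel=channel, fluid=fluid)

    @property
    def q_display(self) -> float:
        """Flow rate rounded to the nearest 1 µL/hr for reporting."""
        return round(self.q_ul_hr)


def cells_per_chip(seeding_density: float, growth_area: float) -> int:
    """Number of cells seeded on a chip: density (cells/cm²) × area (cm²)."""
    if seeding_density < 0.0 or growth_area < 0.0:
        raise InvalidParameterError("seeding density and growth area must be >= 0")
    return round(seeding_density * growth_area)


def duct_shear_correction(aspect_ratio: float, n_terms: int = 200) -> float:
    """Exact rectangular-duct correction to the parallel-plate wall shear.

    Returns f such that the true mid-floor shear of a rectangular duct of
    width/height ratio ``aspect_ratio`` is f · 6µQ/(wh²).  Diagnostic only:
    the parallel-plate value is the package-wide reference because it is the
    convention of the flow-chamber literature.  From the Fourier solution of
    µ∇²u = −G on the rectangle (half-height a, half-width b):

        τ_centre = G a (1 − S_τ),  S_τ = (8/π²) Σ_odd sech(nπb/2a)/n²
        Q = (4Ga³b/3µ)(1 − S_Q),   S_Q = (192a/π⁵b) Σ_odd tanh(nπb/2a)/n⁵

    so f = (1 − S_τ)/(1 − S_Q); f → 1 as the aspect ratio grows.
    """
    if aspect_ratio <= 0.0:
        raise InvalidParameterError(f"aspect ratio must be > 0, got {aspect_ratio}")
    b_over_a = aspect_ratio  # (w/2)/(h/2)
    s_tau = 0.0
    s_q = 0.0
    for k in range(n_terms):
        n = 2 * k + 1
        arg = n * math.pi * b_over_a / 2.0
        # sech overflows for large arg; it is then numerically zero.
        sech = 0.0 if arg > 700.0 else 1.0 / math.cosh(arg)
        s_tau += sech / n**2
        s_q += math.tanh(arg) / n**5
    s_tau *= 8.0 / math.pi**2
    s_q *= 192.0 / (math.pi**5 * b_over_a)
    return (1.0 - s_tau) / (1.0 - s_q)
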