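"""Closed-form hydraulics: parallel-plate relations, profiles, unit safety."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from gutchip import (
    ChannelSpec,
    FlowCondition,
    FluidProperties,
    InvalidParameterError,
    bulge_model_cell_shear,
    cells_per_chip,
    culture_medium,
    duct_shear_correction,
    fabricated_channel,
    flow_rate_for_wall_shear,
    inlet_velocity_profile,
    reynolds_number,
    wall_shear_stress,
)


@pytest.fixture(scope="module")
def ch():
    return fabricated_channel()


@pytest.fixture(scope="module")
def med():
    return culture_medium()


class TestWallShear:
    def test_polarization_flow_rate(self, ch, med):
        # tau_w = 0.02 dyn/cm2 corresponds to ~29 uL/hr in the fabricated chip
        q = flow_rate_for_wall_shear(0.02, ch, med)
        assert q == pytest.approx(29.0, abs=0.5)
        # ... which is about 0.5 uL/min
        assert q / 60.0 == pytest.approx(0.5, abs=0.02)

    def test_reduced_flow_wall_shear(self, ch, med):
        assert wall_shear_stress(18.0, ch, med) == pytest.approx(0.0124, abs=1e-4)

    def test_zero_flow(self, ch, med):
        assert wall_shear_stress(0.0, ch, med) == 0.0
        assert flow_rate_for_wall_shear(0.0, ch, med) == 0.0

    @given(q=st.floats(min_value=1e-2, max_value=1e3))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, q):
        ch, med = fabricated_channel(), culture_medium()
        back = flow_rate_for_wall_shear(wall_shear_stress(q, ch, med), ch, med)
        assert back == pytest.approx(q, rel=1e-9)

    def test_monotonicity(self, ch, med):
        taus = [wall_shear_stress(q, ch, med) for q in (1.0, 5.0, 29.0, 100.0)]
        assert all(a < b for a, b in zip(taus, taus[1:]))
        thick = FluidProperties(density=1.0, dynamic_viscosity=2 * med.dynamic_viscosity)
        assert wall_shear_stress(29.0, ch, thick) > wall_shear_stress(29.0, ch, med)
        tallch = ChannelSpec(width=ch.width, height=2 * ch.height, length=ch.length)
        assert wall_shear_stress(29.0, tallch, med) < wall_shear_stress(29.0, ch, med)

    def test_negative_flow_rejected(self, ch, med):
        with pytest.raises(InvalidParameterError):
            wall_shear_stress(-1.0, ch, med)


class TestUnits:
    def test_viscosity_unit_safety(self, ch):
        a = FluidProperties.from_viscosity(9.3e-8, "N.s/cm2")
        b = FluidProperties.from_viscosity(9.3e-3, "dyn.s/cm2")
        c = FluidProperties.from_viscosity(0.93, "cP")
        assert a.dynamic_viscosity == pytest.approx(9.3e-3)
        for other in (b, c):
            assert wall_shear_stress(29.0, ch, a) == pytest.approx(
                wall_shear_stress(29.0, ch, other)
            )

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unknown viscosity unit"):
            FluidProperties.from_viscosity(1.0, "furlong")

    def test_invalid_fluid(self):
        with pytest.raises(InvalidParameterError):
            FluidProperties(density=-1.0)
        with pytest.raises(InvalidParameterError):
            FluidProperties(dynamic_viscosity=0.0)


class TestBulgeModel:
    @pytest.mark.parametrize(
        "tau_w,expected", [(0.02, 0.06), (0.0, 0.0), (0.0124, 0.0372)]
    )
    def test_three_times_wall_shear(self, tau_w, expected):
        assert bulge_model_cell_shear(tau_w) == pytest.approx(expected)


class TestInletProfile:
    def test_no_slip_and_peak(self, ch):
        h = ch.height
        assert inlet_velocity_profile(0.0, 29.0, ch) == 0.0
        assert inlet_velocity_profile(h, 29.0, ch) == 0.0
        q_cgs = 29.0 * 1e-3 / 3600.0
        mean_u = q_cgs / (ch.width * ch.height)
        assert inlet_velocity_profile(h / 2, 29.0, ch) == pytest.approx(1.5 * mean_u)

    def test_flux_normalization(self, ch):
        val, _ = quad(lambda z: inlet_velocity_profile(z, 29.0, ch) * ch.width, 0, ch.height)
        assert val == pytest.approx(29.0 * 1e-3 / 3600.0, rel=1e-6)

    def test_outside_channel_rejected(self, ch):
        with pytest.raises(InvalidParameterError):
            inlet_velocity_profile(-1e-4, 29.0, ch)


class TestReynolds:
    def test_creeping_regime(self, ch, med):
        # independent hand evaluation of rho*U*h/mu with U = Q/(w h)
        q_cgs = 29.0 * 1e-3 / 3600.0
        expected = med.density * (q_cgs / (ch.width * ch.height)) * ch.height / med.dynamic_viscosity
        re = reynolds_number(29.0, ch, med)
        assert re == pytest.approx(expected, rel=1e-12)
        assert re == pytest.approx(8.7e-3, rel=0.02)
        assert re < 1.0

    def test_linearity_and_zero(self, ch, med):
        assert reynolds_number(0.0, ch, med) == 0.0
        assert reynolds_number(58.0, ch, med) == pytest.approx(
            2 * reynolds_number(29.0, ch, med)
        )


class TestCellsPerChip:
    def test_chip_seeding(self):
        assert cells_per_chip(2e5, 0.32) == 64000

    def test_degenerate_and_scaling(self):
        assert cells_per_chip(2e5, 0.0) == 0
        assert cells_per_chip(2e6, 0.32) == 10 * cells_per_chip(2e5, 0.32)


class TestFlowCondition:
    def test_derived_wall_shear_cached(self, ch, med):
        fc = FlowCondition(q_ul_hr=29.0, channel=ch, fluid=med)
        assert fc.tau_w == pytest.approx(wall_shear_stress(29.0, ch, med), rel=1e-12)
        assert fc.q_display == 29

    def test_inconsistent_pair_rejected(self, ch, med):
        with pytest.raises(InvalidParameterError, match="inconsistent"):
            FlowCondition(q_ul_hr=29.0, tau_w=0.5, channel=ch, fluid=med)

    def test_from_wall_shear(self, ch, med):
        fc = FlowCondition.from_wall_shear(0.0124, ch, med)
        assert fc.q_display == 18


class TestChannel:
    def test_narrow_channel_warns(self):
        with pytest.warns(UserWarning, match="parallel-plate"):
            ChannelSpec(width=0.01, height=0.015, length=1.2)

    def test_invalid_dimension(self):
        with pytest.raises(InvalidParameterError):
            ChannelSpec(width=0.0, height=0.015, length=1.2)


class TestDuctCorrection:
    def test_wide_limit_is_parallel_plate(self):
        assert duct_shear_correction(1e3) == pytest.approx(1.0, abs=1e-3)

    def test_fabricated_aspect_is_modest_correction(self, ch):
        f = duct_shear_correction(ch.aspect_ratio)
        assert 1.0 < f < 1.2
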