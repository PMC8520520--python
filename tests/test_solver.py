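"""Flow solver: analytic validation, conservation, linearity, determinism."""

import numpy as np
import pytest

from gutchip import (
    ConfigError,
    SolverConfig,
    SolverError,
    build_domain,
    cell_array,
    empty_domain,
    floor_shear_profile,
    morphology_defaults,
    solve_flow,
    validate_against_analytic,
    wall_shear_stress,
)

COARSE = SolverConfig(grid_spacing_um=2.0)


def coarse_domain(channel, n_cells=1, res=2.0):
    return build_domain(
        channel, cell_array(n_cells, gap_um=16.0 if n_cells > 1 else None),
        morphology_defaults("small"), resolution_um=res,
    )


class TestAnalyticValidation:
    def test_refinement_study(self):
        rep = validate_against_analytic()
        assert rep.monotone
        assert all(a > b for a, b in zip(rep.floor_shear_errors, rep.floor_shear_errors[1:]))
        assert rep.l2_velocity_errors[-1] < 0.01
        assert rep.floor_shear_errors[-1] < 0.01
        assert rep.passed

    def test_zero_flow_gives_zero_field(self, channel, medium):
        dom = empty_domain(channel, resolution_um=15.0)
        fld = solve_flow(dom, 0.0, medium, SolverConfig(grid_spacing_um=15.0))
        assert np.allclose(fld.u, 0.0) and np.allclose(fld.w, 0.0)


class TestConservation:
    def test_flux_through_every_cross_section(self, solves):
        fld = solves.field("small", q=29.0)
        flux = fld.flux_per_column_cm2_s() * fld.domain.channel.width
        q_cgs = 29.0 * 1e-3 / 3600.0
        assert np.abs(flux - q_cgs).max() / q_cgs < 1e-3

    def test_realized_flow_rate(self, solves):
        fld = solves.field("small", q=29.0)
        assert fld.q_realized_ul_hr == pytest.approx(29.0, rel=1e-3)

    def test_divergence_within_tolerance(self, solves):
        fld = solves.field("small", q=29.0)
        assert fld.max_rel_divergence <= fld.config.divergence_tolerance


class TestBoundaryConditions:
    def test_no_slip_on_walls_and_cells(self, solves):
        fld = solves.field("small", q=29.0)
        solid = fld.solid
        # faces adjacent to solid cells carry exactly zero velocity
        u_solid = np.zeros_like(fld.u, dtype=bool)
        u_solid[1:-1, :] = solid[:-1, :] | solid[1:, :]
        assert np.all(fld.u[u_solid] == 0.0)
        assert np.all(fld.w[:, 0] == 0.0) and np.all(fld.w[:, -1] == 0.0)

    def test_outlet_gauge_pressure_zero(self, solves):
        fld = solves.field("small", q=29.0)
        assert np.nanmean(fld.p[-1, :]) == pytest.approx(0.0, abs=1e-12)


class TestStokesStructure:
    def test_linearity_in_flow_rate(self, channel, medium):
        dom = coarse_domain(channel)
        f1 = solve_flow(dom, 29.0, medium, COARSE)
        f2 = solve_flow(dom, 58.0, medium, COARSE)
        scale = np.abs(f1.u).max()
        assert np.abs(f2.u - 2 * f1.u).max() / (2 * scale) < 1e-10
        assert np.abs(f2.w - 2 * f1.w).max() / (2 * scale) < 1e-10

    def test_bit_identical_reruns(self, channel, medium):
        dom = coarse_domain(channel)
        f1 = solve_flow(dom, 29.0, medium, COARSE)
        f2 = solve_flow(dom, 29.0, medium, COARSE)
        assert np.array_equal(f1.u, f2.u)
        assert np.array_equal(f1.w, f2.w)
        assert np.array_equal(f1.p[~np.isnan(f1.p)], f2.p[~np.isnan(f2.p)])

    def test_navier_stokes_matches_stokes_at_low_reynolds(self, channel, medium):
        dom = coarse_domain(channel)
        f_st = solve_flow(dom, 29.0, medium, COARSE)
        cfg = SolverConfig(grid_spacing_um=2.0, advection="navier_stokes")
        f_ns = solve_flow(dom, 29.0, medium, cfg)
        assert f_ns.iterations >= 2
        rel = np.abs(f_ns.u - f_st.u).max() / np.abs(f_st.u).max()
        assert rel < 1e-3  # Re ~ 1e-2: inertia is a negligible correction


class TestConfigValidation:
    def test_divergence_tolerance_ceiling(self):
        with pytest.raises(ConfigError):
            SolverConfig(divergence_tolerance=1e-3)

    def test_under_resolved_geometry_rejected(self, channel, medium):
        dom = build_domain(channel, cell_array(1), morphology_defaults("small"), resolution_um=2.0)
        with pytest.raises(ConfigError, match="fewer than 8"):
            solve_flow(dom, 29.0, medium, SolverConfig(grid_spacing_um=20.0))

    def test_negative_flow_rejected(self, channel, medium):
        dom = empty_domain(channel, resolution_um=15.0)
        with pytest.raises(SolverError):
            solve_flow(dom, -1.0, medium, SolverConfig(grid_spacing_um=15.0))


class TestFieldExports:
    def test_hdf5_round_trip(self, solves, tmp_path):
        import h5py

        fld = solves.field("small", q=29.0)
        path = tmp_path / "field.h5"
        fld.to_hdf5(str(path))
        with h5py.File(path) as fh:
            assert np.array_equal(fh["u"][...], fld.u)
            assert fh.attrs["q_requested_ul_hr"] == 29.0

    def test_vtk_is_ascii(self, channel, medium, tmp_path):
        dom = empty_domain(channel, resolution_um=15.0)
        fld = solve_flow(dom, 29.0, medium, SolverConfig(grid_spacing_um=15.0))
        path = tmp_path / "field.vtk"
        fld.to_vtk(str(path))
        head = path.read_text().splitlines()
        assert head[0].startswith("# vtk DataFile")
        assert "ASCII" in head[2]


class TestFloorShear:
    def test_empty_channel_floor_shear_uniform(self, channel, medium):
        dom = empty_domain(channel, resolution_um=3.75)
        fld = solve_flow(dom, 29.0, medium, SolverConfig(grid_spacing_um=3.75))
        tau = floor_shear_profile(fld, medium)
        ref = wall_shear_stress(29.0, channel, medium)
        core = tau[fld.nx // 4 : -fld.nx // 4]
        assert np.abs(core - ref).max() / ref < 0.02
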