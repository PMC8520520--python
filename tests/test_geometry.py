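"""Cell shapes, domain assembly, rasterization and boundary tagging."""

import math

import numpy as np
import pytest

from gutchip import (
    CellMorphology,
    DomainSpec,
    GeometryError,
    build_cell_profile,
    build_domain,
    cell_array,
    empty_domain,
    export_domain,
    fabricated_channel,
    morphology_defaults,
    tag_boundary_faces,
)


@pytest.fixture(scope="module")
def ch():
    return fabricated_channel()


class TestMorphologyDefaults:
    @pytest.mark.parametrize(
        "label,hc,wc,cap",
        [
            ("small", 13.0, 26.0, "hemispherical_bulge"),
            ("medium", 27.0, 18.0, "rounded_column"),
            ("tall", 34.0, 12.0, "rounded_column"),
        ],
    )
    def test_reference_dimensions(self, label, hc, wc, cap):
        m = morphology_defaults(label)
        assert (m.cell_height_um, m.cell_width_um, m.cap_shape) == (hc, wc, cap)

    def test_overrides(self):
        m = morphology_defaults("tall", {"height_um": 30.0, "width_um": 15.0})
        assert m.cell_height_um == 30.0 and m.cell_width_um == 15.0

    def test_unknown_label(self):
        with pytest.raises(GeometryError, match="unknown morphology"):
            morphology_defaults("giant")


class TestCellProfile:
    def test_small_default_is_half_circle(self):
        # chord = 2 x height forces radius = height: a semicircular bulge
        m = morphology_defaults("small")
        curve = build_cell_profile(m, n_points=401)
        r = np.hypot(curve[:, 0], curve[:, 1])
        interior = curve[:, 1] > 0.1
        assert np.allclose(r[interior], 13.0, rtol=5e-3)

    @pytest.mark.parametrize("label", ["small", "medium", "tall"])
    def test_profile_contract(self, label):
        m = morphology_defaults(label)
        curve = build_cell_profile(m, n_points=801)
        assert curve[0, 1] == 0.0 and curve[-1, 1] == 0.0
        assert curve[:, 1].max() == pytest.approx(m.cell_height_um, rel=5e-3)
        footprint = curve[:, 0].max() - curve[:, 0].min()
        assert footprint == pytest.approx(m.cell_width_um, rel=5e-3)

    def test_degenerate_rejected(self):
        with pytest.raises(GeometryError):
            CellMorphology("x", cell_height_um=10.0, cell_width_um=0.0, cap_shape="rounded_column")
        with pytest.raises(GeometryError):
            build_cell_profile(morphology_defaults("small"), n_points=2)

    def test_reentrant_bulge_rejected(self):
        with pytest.raises(GeometryError, match="bulge"):
            CellMorphology("x", cell_height_um=20.0, cell_width_um=10.0, cap_shape="hemispherical_bulge")

    @pytest.mark.parametrize("label", ["small", "medium", "tall"])
    def test_half_width_inverts_elevation(self, label):
        m = morphology_defaults(label)
        for z in np.linspace(0.0, m.cell_height_um * 0.999, 40):
            hw = m.half_width_at(z)
            if hw > 1e-9:
                # the surface at x = hw sits at elevation z (within sampling)
                assert m.elevation_um(hw * 0.999) >= z - 1e-6


class TestDomainAssembly:
    def test_single_cell_role(self, ch):
        dom = build_domain(ch, cell_array(1), morphology_defaults("small"))
        assert dom.position_roles == {0: "outer"}

    def test_array_roles_by_streamwise_order(self, ch):
        dom = build_domain(ch, cell_array(5, gap_um=6.0), morphology_defaults("tall"))
        roles = [dom.position_roles[i] for i in range(5)]
        assert roles == ["outer", "inner", "inner", "inner", "inner"]

    def test_mirror_swaps_outer_to_opposite_end(self, ch):
        dom = build_domain(ch, cell_array(3), morphology_defaults("small"))
        mirrored = dom.mirrored()
        # cell order reverses; the new outer is the old last cell's position
        assert mirrored.position_roles[0] == "outer"
        old_last_x = dom.cells[-1][0]
        assert mirrored.cells[0][0] == pytest.approx(dom.length_um - old_last_x)

    def test_buffer_depth(self, ch):
        m = morphology_defaults("small")
        dom = build_domain(ch, cell_array(1), m)
        first_lo = dom.cells[0][0] - m.cell_width_um / 2
        assert first_lo >= 5 * m.cell_width_um - 1e-9

    def test_overlapping_cells_rejected(self, ch):
        m = morphology_defaults("small")
        with pytest.raises(GeometryError, match="overlap"):
            DomainSpec(
                channel=ch,
                cells=((200.0, m), (210.0, m)),
                length_um=500.0,
                resolution_um=1.0,
            )

    def test_too_tall_cell_rejected(self, ch):
        m = morphology_defaults("tall", {"height_um": 200.0})
        with pytest.raises(GeometryError, match="channel"):
            DomainSpec(channel=ch, cells=((300.0, m),), length_um=600.0, resolution_um=1.0)

    def test_array_exceeding_channel_rejected(self, ch):
        with pytest.raises(GeometryError):
            build_domain(ch, cell_array(100, gap_um=200.0), morphology_defaults("small"))

    def test_resolution_floor(self, ch):
        with pytest.raises(GeometryError, match="resolution"):
            build_domain(ch, cell_array(1), morphology_defaults("tall"), resolution_um=5.0)


class TestRasterization:
    @pytest.mark.parametrize("label", ["small", "medium", "tall"])
    def test_mask_area_converges_first_order(self, ch, label):
        m = morphology_defaults(label)
        dom = build_domain(ch, cell_array(1), m)
        exact = m.profile_area_um2()
        errs = {}
        for res in (4.0, 1.0):
            nx, nz, dx, dz = dom.grid_shape(res)
            area = dom.solid_mask(res).sum() * dx * dz
            errs[res] = abs(area - exact) / exact
        assert errs[1.0] < errs[4.0]
        assert errs[1.0] < 0.05

    def test_boundary_tag_partition(self, ch):
        dom = build_domain(ch, cell_array(2, gap_um=16.0), morphology_defaults("small"), resolution_um=2.0)
        tags = tag_boundary_faces(dom, 2.0)
        tagged = [f for faces in tags.values() for f in faces]
        assert len(tagged) == len(set(tagged))  # no face carries two tags
        # brute-force boundary of the fluid region from the mask
        mask = dom.solid_mask(2.0)
        nx, nz, _, _ = dom.grid_shape(2.0)
        fluid = ~mask
        expected = set()
        for i in range(nx):
            for j in range(nz):
                if not fluid[i, j]:
                    continue
                if i == 0 or not fluid[i - 1, j]:
                    expected.add(("x", i, j))
                if i == nx - 1 or not fluid[i + 1, j]:
                    expected.add(("x", i + 1, j))
                if j == 0 or not fluid[i, j - 1]:
                    expected.add(("z", i, j))
                if j == nz - 1 or not fluid[i, j + 1]:
                    expected.add(("z", i, j + 1))
        assert set(tagged) == expected
        assert len(tags["cell_surface(0)"]) > 0 and len(tags["cell_surface(1)"]) > 0

    def test_export_is_plain_text(self, ch, tmp_path):
        dom = build_domain(ch, cell_array(1), morphology_defaults("small"), resolution_um=2.0)
        path = tmp_path / "domain.txt"
        export_domain(dom, str(path), 4.0)
        text = path.read_text()
        assert text.startswith("# gutchip domain export")
        assert "face inlet" in text and "face cell_surface(0)" in text


class TestEmptyDomain:
    def test_empty_domain_has_no_cells(self, ch):
        dom = empty_domain(ch)
        assert dom.cells == ()
        assert not dom.solid_mask(15.0).any()
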