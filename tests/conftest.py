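"""Shared fixtures: channel/fluid defaults and a session-wide solve cache.

Flow solves are the expensive part of the suite; the cache keys them by
(morphology, arrangement, flow rate, resolution, viscosity factor) so that
acceptance and property tests share fields instead of re-solving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest

from gutchip import (
    FluidProperties,
    SolverConfig,
    build_domain,
    cell_array,
    cell_shear_summary,
    culture_medium,
    fabricated_channel,
    morphology_defaults,
    solve_flow,
)

#: default grid spacing per (label, n_cells); tall arrays need finer grids
#: to resolve their 6 µm inter-cell gaps by >= 8 elements.
def _default_res(label: str, n_cells: int) -> float:
    if n_cells > 1:
        gap = morphology_defaults(label).cell_width_um / 2.0
        return min(1.0, gap / 8.0)
    return 1.0


@dataclass
class SolveCache:
    channel: object
    fluid: object
    _fields: dict = field(default_factory=dict)
    _reports: dict = field(default_factory=dict)

    def key(self, label, n_cells, q, res, mu_factor):
        return (label, n_cells, round(q, 6), res, mu_factor)

    def field(self, label, n_cells=1, q=29.0, res=None, mu_factor=1.0):
        res = res if res is not None else _default_res(label, n_cells)
        k = self.key(label, n_cells, q, res, mu_factor)
        if k not in self._fields:
            fluid = self.fluid
            if mu_factor != 1.0:
                fluid = FluidProperties(
                    density=fluid.density,
                    dynamic_viscosity=fluid.dynamic_viscosity * mu_factor,
                )
            morph = morphology_defaults(label)
            dom = build_domain(
                self.channel, cell_array(n_cells), morph, resolution_um=res
            )
            cfg = SolverConfig(grid_spacing_um=res)
            self._fields[k] = solve_flow(dom, q, fluid, cfg)
        return self._fields[k]

    def report(self, label, n_cells=1, q=29.0, res=None, mu_factor=1.0):
        res = res if res is not None else _default_res(label, n_cells)
        k = self.key(label, n_cells, q, res, mu_factor)
        if k not in self._reports:
            fld = self.field(label, n_cells, q, res, mu_factor)
            self._reports[k] = cell_shear_summary(fld)
        return self._reports[k]


@pytest.fixture(scope="session")
def channel():
    return fabricated_channel()


@pytest.fixture(scope="session")
def medium():
    return culture_medium()


@pytest.fixture(scope="session")
def solves(channel, medium):
    return SolveCache(channel=channel, fluid=medium)
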