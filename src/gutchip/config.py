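"""YAML/JSON run-configuration loading.

A config file can override the fluid, the channel, the morphology
dimensions and the array layout, e.g.::

    fluid: {density: 1.0, viscosity: 9.3e-8, viscosity_units: N.s/cm2}
    channel: {width_um: 1000, height_um: 150, length_um: 12000}
    morphologies:
      tall: {height_um: 34, width_um: 12, cap_shape: rounded_column}
    array: {n_cells: 5, gap_um: 6}
    resolution_um: 1.0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import CellArraySpec, CellMorphology, cell_array, morphology_defaults
from .hydraulics import ChannelSpec, FluidProperties, culture_medium, fabricated_channel
from .units import um_to_cm


def fluid_from_config(cfg: dict | None) -> FluidProperties:
    if not cfg:
        return culture_medium()
    units = cfg.get("viscosity_units", "dyn.s/cm2")
    return FluidProperties.from_viscosity(
        cfg.get("viscosity", 9.3e-3), units, density=cfg.get("density", 1.0)
    )


def _length_cm(cfg: dict, name: str, default_cm: float) -> float:
    if f"{name}_cm" in cfg:
        return float(cfg[f"{name}_cm"])
    if f"{name}_um" in cfg:
        return um_to_cm(float(cfg[f"{name}_um"]))
    if name in cfg:  # bare value: cm (internal unit system)
        return float(cfg[name])
    return default_cm


def channel_from_config(cfg: dict | None) -> ChannelSpec:
    base = fabricated_channel()
    if not cfg:
        return base
    return ChannelSpec(
        width=_length_cm(cfg, "width", base.width),
        height=_length_cm(cfg, "height", base.height),
        length=_length_cm(cfg, "length", base.length),
    )


@dataclass(frozen=True)
class RunConfig:
    """Materialized run configuration with package defaults filled in."""

    fluid: FluidProperties
    channel: ChannelSpec
    morphologies: dict[str, CellMorphology] = field(default_factory=dict)
    array: CellArraySpec = field(default_factory=lambda: cell_array(1))
    resolution_um: float = 1.0

    def morphology(self, label: str) -> CellMorphology:
        return self.morphologies.get(label) or morphology_defaults(label)


def parse_config(raw: dict) -> RunConfig:
    morphologies = {
        label: morphology_defaults(label, overrides)
        for label, overrides in (raw.get("morphologies") or {}).items()
    }
    arr_cfg = raw.get("array") or {}
    array = cell_array(arr_cfg.get("n_cells", 1), arr_cfg.get("gap_um"))
    return RunConfig(
        fluid=fluid_from_config(raw.get("fluid")),
        channel=channel_from_config(raw.get("channel")),
        morphologies=morphologies,
        array=array,
        resolution_um=float(raw.get("resolution_um", 1.0)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)
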