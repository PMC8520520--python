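"""Parametric cell shapes and flow-domain construction.

Epithelial cells on the channel floor are modelled as two-dimensional
obstacles in the longitudinal x–z plane (flow × height), the same plane in
which the parallel-plate wall-shear formula lives; the spanwise direction is
treated as uniform.  Three reference morphologies track the polarization of
Caco-2 cells: a low hemispherical *small* cell (bulge-like, early culture),
an intermediate *medium* cell, and a *tall* columnar cell (fully polarized
enterocyte).  Cells are placed singly or as short streamwise arrays; the
first cell met by the flow is tagged ``outer`` and sheltered downstream
cells ``inner``.

All lengths are µm at the user surface and cm internally; the solver
consumes the domain through :meth:`DomainSpec.solid_mask` (stair-step
rasterization, refined by the grid spacing) and
:func:`tag_boundary_faces`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .hydraulics import ChannelSpec
from .units import cm_to_um

MorphologyLabel = Literal["small", "medium", "tall"]
CapShape = Literal["hemispherical_bulge", "rounded_column"]


class GeometryError(ValueError):
    """Invalid or inconsistent cell/domain geometry."""


@dataclass(frozen=True)
class CellMorphology:
    """A parametric cell cross-section on the channel floor.

    ``hemispherical_bulge`` is a circular arc of height ``cell_height_um``
    over a chord ``cell_width_um`` (a half-circle when the chord equals
    twice the height); ``rounded_column`` is a rectangle capped by a
    semicircular/elliptical top, total height ``cell_height_um``.
    """

    label: str
    cell_height_um: float
    cell_width_um: float
    cap_shape: CapShape

    def __post_init__(self) -> None:
        if self.cell_height_um <= 0.0 or self.cell_width_um <= 0.0:
            raise GeometryError(
                f"cell height/width must be > 0, got "
                f"({self.cell_height_um}, {self.cell_width_um}) µm"
            )
        if self.cap_shape not in ("hemispherical_bulge", "rounded_column"):
            raise GeometryError(f"unknown cap shape {self.cap_shape!r}")
        if self.cap_shape == "hemispherical_bulge" and self.cell_width_um < self.cell_height_um:
            # an arc segment taller than half its chord's circle is re-entrant
            raise GeometryError(
                "hemispherical bulge requires width >= height "
                f"(got {self.cell_width_um} < {self.cell_height_um} µm)"
            )

    def elevation_um(self, x_um: np.ndarray | float) -> np.ndarray | float:
        """Surface elevation z(x) in µm for x in µm relative to the cell centre.

        Zero outside the footprint |x| > width/2.
        """
        x = np.asarray(x_um, dtype=float)
        hw = self.cell_width_um / 2.0
        hc = self.cell_height_um
        inside = np.abs(x) <= hw
        z = np.zeros_like(x)
        if self.cap_shape == "hemispherical_bulge":
            # circular segment: radius from chord 2·hw and height hc
            r = (hc**2 + hw**2) / (2.0 * hc)
            z0 = r - hc  # centre depth below the floor
            with np.errstate(invalid="ignore"):
                z = np.where(inside, np.sqrt(np.maximum(r**2 - x**2, 0.0)) - z0, 0.0)
            z = np.maximum(z, 0.0)
        else:
            cap = min(hw, hc)
            shoulder = hc - cap
            with np.errstate(invalid="ignore"):
                ell = cap * np.sqrt(np.maximum(1.0 - (x / hw) ** 2, 0.0))
            z = np.where(inside, shoulder + ell, 0.0)
        if np.isscalar(x_um):
            return float(z)
        return z

    def half_width_at(self, z_um: float) -> float:
        """Half-width of the cross-section at elevation z (µm); 0 above apex.

        Inverse of :meth:`elevation_um`, used for sub-grid wall distances on
        the cell flanks.
        """
        hw = self.cell_width_um / 2.0
        hc = self.cell_height_um
        if z_um < 0.0 or z_um >= hc:
            return 0.0
        if self.cap_shape == "hemispherical_bulge":
            r = (hc**2 + hw**2) / (2.0 * hc)
            z0 = r - hc
            val = r**2 - (z_um + z0) ** 2
            return math.sqrt(val) if val > 0.0 else 0.0
        cap = min(hw, hc)
        shoulder = hc - cap
        if z_um <= shoulder:
            return hw
        frac = (z_um - shoulder) / cap
        return hw * math.sqrt(max(1.0 - frac**2, 0.0))

    def profile_area_um2(self) -> float:
        """Analytic cross-section area in µm² (convergence oracle for masks)."""
        hw = self.cell_width_um / 2.0
        hc = self.cell_height_um
        if self.cap_shape == "hemispherical_bulge":
            r = (hc**2 + hw**2) / (2.0 * hc)
            # circular-segment area
            return r**2 * math.acos((r - hc) / r) - (r - hc) * math.sqrt(
                2.0 * r * hc - hc**2
            )
        cap = min(hw, hc)
        shoulder = hc - cap
        return self.cell_width_um * shoulder + math.pi * hw * cap / 2.0


_DEFAULTS: dict[str, tuple[float, float, CapShape]] = {
    # label: (height µm, width µm, cap shape)
    "small": (13.0, 26.0, "hemispherical_bulge"),
    "medium": (27.0, 18.0, "rounded_column"),
    "tall": (34.0, 12.0, "rounded_column"),
}


def morphology_defaults(
    label: str, overrides: dict | None = None
) -> CellMorphology:
    """Reference morphology for a label in {small, medium, tall}.

    Heights follow the measured monolayer heights (13/27/34 µm); the small
    cell is a half-circular bulge (width = 2 × height) and the taller,
    polarizing morphologies narrow laterally as columnar cells do.  Every
    field can be overridden via ``overrides`` keys ``height_um``,
    ``width_um``, ``cap_shape``.
    """
    try:
        hc, wc, cap = _DEFAULTS[label]
    except KeyError:
        raise GeometryError(
            f"unknown morphology label {label!r}; expected one of {sorted(_DEFAULTS)}"
        ) from None
    overrides = overrides or {}
    return CellMorphology(
        label=label,
        cell_height_um=float(overrides.get("height_um", hc)),
        cell_width_um=float(overrides.get("width_um", wc)),
        cap_shape=overrides.get("cap_shape", cap),
    )


def build_cell_profile(
    morphology: CellMorphology, n_points: int = 200
) -> np.ndarray:
    """Closed planar polyline (x, z) in µm of the cell's exposed surface.

    The curve starts and ends on the channel floor (z = 0) at the footprint
    edges, sampled left to right with ``n_points`` vertices.
    """
    if n_points < 3:
        raise GeometryError(f"need >= 3 points, got {n_points}")
    hw = morphology.cell_width_um / 2.0
    x = np.linspace(-hw, hw, n_points)
    z = np.asarray(morphology.elevation_um(x), dtype=float)
    z[0] = 0.0
    z[-1] = 0.0
    return np.column_stack([x, z])


@dataclass(frozen=True)
class CellArraySpec:
    """Single cell or a short streamwise array of identical cells."""

    arrangement: Literal["single", "array"] = "single"
    n_cells: int = 1
    gap_um: float | None = None  # None -> width/2 default at build time

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise GeometryError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.arrangement == "single" and self.n_cells != 1:
            raise GeometryError("arrangement 'single' requires n_cells == 1")
        if self.arrangement == "array" and self.n_cells < 2:
            raise GeometryError("arrangement 'array' requires n_cells >= 2")
        if self.gap_um is not None and self.gap_um < 0.0:
            raise GeometryError(f"gap must be >= 0, got {self.gap_um}")


def cell_array(n_cells: int, gap_um: float | None = None) -> CellArraySpec:
    """Convenience constructor choosing 'single' vs 'array' from the count."""
    arrangement = "single" if n_cells == 1 else "array"
    return CellArraySpec(arrangement=arrangement, n_cells=n_cells, gap_um=gap_um)


@dataclass(frozen=True)
class DomainSpec:
    """The simulated flow window: channel slice, cell placement, resolution.

    The solver window spans ``length_um`` in x (inlet at x = 0, floor at
    z = 0) with the cells centred; the physical chip channel is much longer
    than the window, which keeps fully developed inlet/outlet conditions
    honest while keeping grids small.  ``position_roles`` maps cell index to
    ``outer`` (first cell met by the flow) or ``inner``.
    """

    channel: ChannelSpec
    cells: tuple[tuple[float, CellMorphology], ...]  # (centre x in µm, shape)
    length_um: float
    resolution_um: float
    position_roles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        h_um = cm_to_um(self.channel.height)
        if self.length_um <= 0.0:
            raise GeometryError(f"domain length must be > 0, got {self.length_um}")
        if self.length_um > cm_to_um(self.channel.length) + 1e-9:
            raise GeometryError(
                f"simulated window ({self.length_um} µm) exceeds channel length "
                f"({cm_to_um(self.channel.length)} µm)"
            )
        spans = []
        for idx, (x0, morph) in enumerate(self.cells):
            if morph.cell_height_um >= h_um:
                raise GeometryError(
                    f"cell {idx}: height {morph.cell_height_um} µm >= channel "
                    f"height {h_um} µm"
                )
            lo = x0 - morph.cell_width_um / 2.0
            hi = x0 + morph.cell_width_um / 2.0
            if lo < 0.0 or hi > self.length_um:
                raise GeometryError(f"cell {idx} extends outside the domain window")
            spans.append((lo, hi, idx))
        spans.sort()
        for (lo_a, hi_a, ia), (lo_b, hi_b, ib) in zip(spans, spans[1:]):
            if hi_a > lo_b + 1e-9:
                raise GeometryError(f"cells {ia} and {ib} overlap")
        if self.cells and not self.position_roles:
            object.__setattr__(self, "position_roles", _roles_by_order(self.cells))
        if self.cells:
            outer = [i for i, r in self.position_roles.items() if r == "outer"]
            if len(outer) != 1:
                raise GeometryError(f"exactly one outer cell expected, got {outer}")

    # --- discretization -------------------------------------------------

    def grid_shape(self, spacing_um: float | None = None) -> tuple[int, int, float, float]:
        """(nx, nz, dx_um, dz_um) for a target spacing (default resolution)."""
        s = spacing_um if spacing_um is not None else self.resolution_um
        h_um = cm_to_um(self.channel.height)
        nz = max(4, round(h_um / s))
        nx = max(4, round(self.length_um / s))
        return nx, nz, self.length_um / nx, h_um / nz

    def solid_mask(self, spacing_um: float | None = None) -> np.ndarray:
        """Boolean (nx, nz) mask of solid cells, True inside an obstacle.

        Stair-step rasterization by cell-centre sampling; the discrete
        obstacle area converges to the analytic profile area as the spacing
        shrinks (first order).
        """
        nx, nz, dx, dz = self.grid_shape(spacing_um)
        xc = (np.arange(nx) + 0.5) * dx
        zc = (np.arange(nz) + 0.5) * dz
        mask = np.zeros((nx, nz), dtype=bool)
        for x0, morph in self.cells:
            elev = np.asarray(morph.elevation_um(xc - x0))
            mask |= zc[None, :] < elev[:, None]
        return mask

    def owner_of_column(self, x_um: float) -> int | None:
        """Index of the cell whose footprint contains x (µm), else None."""
        for idx, (x0, morph) in enumerate(self.cells):
            if abs(x_um - x0) <= morph.cell_width_um / 2.0 + 1e-9:
                return idx
        return None

    def mirrored(self) -> "DomainSpec":
        """The domain reflected in x (flow direction reversed).

        Roles are reassigned, so the outer role moves to the opposite end of
        an array.
        """
        cells = tuple(
            (self.length_um - x0, morph) for x0, morph in reversed(self.cells)
        )
        return replace(self, cells=cells, position_roles={})


def _roles_by_order(
    cells: tuple[tuple[float, CellMorphology], ...]
) -> dict[int, str]:
    order = sorted(range(len(cells)), key=lambda i: cells[i][0])
    roles = {i: "inner" for i in range(len(cells))}
    roles[order[0]] = "outer"
    return roles


def build_domain(
    channel: ChannelSpec,
    array: CellArraySpec,
    morphology: CellMorphology,
    resolution_um: float = 1.0,
    buffer_um: float | None = None,
) -> DomainSpec:
    """Place a single cell or array in a simulation window with clear buffers.

    The array is centred; upstream and downstream buffers default to
    max(5 cell widths, one channel height) so the imposed fully developed
    inlet/outlet profiles are unpolluted by the obstacles (channel-flow
    disturbances decay over a height-scale distance).
    """
    if resolution_um <= 0.0:
        raise GeometryError(f"resolution must be > 0, got {resolution_um}")
    if morphology.cell_width_um / resolution_um < 10.0:
        raise GeometryError(
            f"resolution {resolution_um} µm resolves the {morphology.cell_width_um} µm "
            "cell width by fewer than 10 elements"
        )
    wc = morphology.cell_width_um
    gap = array.gap_um if array.gap_um is not None else wc / 2.0
    if buffer_um is None:
        buffer_um = max(5.0 * wc, cm_to_um(channel.height))
    span = array.n_cells * wc + (array.n_cells - 1) * gap
    length = span + 2.0 * buffer_um
    if length > cm_to_um(channel.length):
        raise GeometryError(
            f"array span {span} µm plus buffers exceeds the channel length "
            f"{cm_to_um(channel.length)} µm"
        )
    first_centre = buffer_um + wc / 2.0
    cells = tuple(
        (first_centre + i * (wc + gap), morphology) for i in range(array.n_cells)
    )
    return DomainSpec(
        channel=channel,
        cells=cells,
        length_um=length,
        resolution_um=resolution_um,
    )


def empty_domain(
    channel: ChannelSpec,
    length_um: float | None = None,
    resolution_um: float = 1.0,
) -> DomainSpec:
    """An obstacle-free window (plane-Poiseuille benchmark geometry)."""
    if length_um is None:
        length_um = 3.0 * cm_to_um(channel.height)
    return DomainSpec(
        channel=channel, cells=(), length_um=length_um, resolution_um=resolution_um
    )


# --- boundary tagging and export ----------------------------------------


def tag_boundary_faces(
    domain: DomainSpec, spacing_um: float | None = None
) -> dict[str, list[tuple[str, int, int]]]:
    """Tag every boundary face of the fluid region with exactly one label.

    Faces are ``("x", i, j)`` (between cell columns i-1 and i) or
    ``("z", i, j)`` (between cell rows j-1 and j).  Labels: ``inlet``,
    ``outlet``, ``top_wall``, ``floor``, ``cell_surface(k)``.  Together the
    tags partition the whole boundary of the fluid domain.
    """
    mask = domain.solid_mask(spacing_um)
    nx, nz, dx, dz = domain.grid_shape(spacing_um)
    fluid = ~mask
    tags: dict[str, list[tuple[str, int, int]]] = {
        "inlet": [],
        "outlet": [],
        "top_wall": [],
        "floor": [],
    }

    def cell_tag(i: int) -> str:
        owner = domain.owner_of_column((i + 0.5) * dx)
        if owner is None:  # staircase edge just outside a footprint
            centres = [abs((i + 0.5) * dx - x0) for x0, _ in domain.cells]
            owner = int(np.argmin(centres))
        return f"cell_surface({owner})"

    for j in range(nz):
        if fluid[0, j]:
            tags["inlet"].append(("x", 0, j))
        if fluid[nx - 1, j]:
            tags["outlet"].append(("x", nx, j))
    for i in range(nx):
        if fluid[i, nz - 1]:
            tags["top_wall"].append(("z", i, nz))
        if fluid[i, 0]:
            tags["floor"].append(("z", i, 0))
        elif mask[i, 0]:
            pass  # solid sits on the floor; not a fluid boundary face
    # fluid/solid interfaces
    for i in range(nx):
        for j in range(nz):
            if not mask[i, j]:
                continue
            t = cell_tag(i)
            if i > 0 and fluid[i - 1, j]:
                tags.setdefault(t, []).append(("x", i, j))
            if i < nx - 1 and fluid[i + 1, j]:
                tags.setdefault(t, []).append(("x", i + 1, j))
            if j < nz - 1 and fluid[i, j + 1]:
                tags.setdefault(t, []).append(("z", i, j + 1))
            if j > 0 and fluid[i, j - 1]:
                tags.setdefault(t, []).append(("z", i, j))
    return tags


def export_domain(domain: DomainSpec, path: str, spacing_um: float | None = None) -> None:
    """Dump the rasterized domain (grid, mask, boundary tags) as plain text."""
    mask = domain.solid_mask(spacing_um)
    nx, nz, dx, dz = domain.grid_shape(spacing_um)
    tags = tag_boundary_faces(domain, spacing_um)
    with open(path, "w") as fh:
        fh.write("# gutchip domain export (stair-step raster)\n")
        fh.write(f"nx {nx} nz {nz} dx_um {dx:.6g} dz_um {dz:.6g}\n")
        fh.write(f"length_um {domain.length_um:.6g} "
                 f"height_um {cm_to_um(domain.channel.height):.6g}\n")
        fh.write("# solid cells (i j)\n")
        for i, j in zip(*np.nonzero(mask)):
            fh.write(f"solid {i} {j}\n")
        fh.write("# boundary faces: tag orientation i j\n")
        for tag, faces in tags.items():
            for orient, i, j in faces:
                fh.write(f"face {tag} {orient} {i} {j}\n")


__all__ = [
    "CellMorphology",
    "CellArraySpec",
    "DomainSpec",
    "GeometryError",
    "build_cell_profile",
    "build_domain",
    "cell_array",
    "empty_domain",
    "export_domain",
    "morphology_defaults",
    "tag_boundary_faces",
]
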