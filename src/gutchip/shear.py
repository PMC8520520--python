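"""Shear stress on cell surfaces and the per-condition summary table.

A cell protruding from the channel floor reaches into faster-moving fluid,
so the shear stress on its exposed (apical) surface exceeds the wall shear
τw of the empty channel.  This module samples the viscous shear
µ ∂u_t/∂n (magnitude) along every tagged surface of a solved flow field,
reports per-cell peak and mean values, and normalizes them by the analytic
parallel-plate τw for the same flow rate — the convention under which the
bulge model predicts a peak ratio of ≈ 3 for low hemispherical cells, while
tall columnar (polarized) cells exceed 4.

Numerical details: the solver represents cell surfaces stair-step, and raw
face-by-face stresses spike at staircase corners (a rasterization artifact,
visible as single-sample outliers at the flank/cap junction).  Cell-surface
shear is therefore evaluated on the *analytic* profile curve: at each
surface point the tangential velocity is probed a small normal offset into
the fluid (default 1.5 and 3 grid spacings) and differenced one-sidedly
through the no-slip wall with a quadratic stencil, which is exact for
locally parabolic profiles and smooth along the surface.  The two samples
adjacent to each floor contact line are excluded from the peak
(contact-corner singularity), and a short moving average (window 3) guards
against residual grid-scale oscillation.  Means are arclength-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import CellArraySpec, CellMorphology, DomainSpec, build_domain, cell_array
from .hydraulics import ChannelSpec, FluidProperties, culture_medium, wall_shear_stress
from .solver import FlowField, SolverConfig, SolverError, solve_flow


@dataclass(frozen=True)
class SurfaceSample:
    """One shear sample on a cell surface."""

    x_cm: float
    z_cm: float
    tau: float
    face_length_cm: float  # arclength carried by this sample
    orientation: str  # outward-normal angle bucket or face type


@dataclass(frozen=True)
class CellShear:
    """Shear summary over one cell's exposed surface."""

    index: int
    role: str
    tau_c_peak: float
    tau_c_mean: float
    n_samples: int


@dataclass(frozen=True)
class ShearReport:
    """Per-cell shear stresses for one solved condition (one table row set)."""

    per_cell: tuple[CellShear, ...]
    tau_w_reference: float
    q_ul_hr: float
    morphology_label: str
    arrangement: str

    @property
    def tau_c_peak(self) -> float:
        """Headline cell shear: the outer cell's peak."""
        return self.outer.tau_c_peak

    @property
    def outer(self) -> CellShear:
        return next(c for c in self.per_cell if c.role == "outer")

    @property
    def ratio_peak(self) -> float:
        """Peak amplification τc/τw with the analytic parallel-plate τw."""
        return self.tau_c_peak / self.tau_w_reference

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "morphology": self.morphology_label,
                "arrangement": self.arrangement,
                "role": c.role,
                "cell_index": c.index,
                "Q_uL_hr": self.q_ul_hr,
                "tau_w": self.tau_w_reference,
                "tau_c_peak": c.tau_c_peak,
                "tau_c_mean": c.tau_c_mean,
                "ratio": c.tau_c_peak / self.tau_w_reference,
            }
            for c in self.per_cell
        ]
        return pd.DataFrame(rows)


def _require_converged(fld: FlowField) -> None:
    if not fld.converged:
        raise SolverError(
            "refusing to extract shear from an unconverged field "
            f"(divergence {fld.max_rel_divergence:.3e})"
        )


def _interp_velocity(fld: FlowField, pts: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of (u, w) at arbitrary points (n, 2) in cm.

    Each staggered component is interpolated on its own node lattice; points
    outside a lattice are clamped to its edge (only relevant within half a
    spacing of the walls, where velocities are ~0 anyway).
    """
    dx, dz = fld.dx_cm, fld.dz_cm
    nx, nz = fld.nx, fld.nz

    def bilin(arr, x0, z0, ddx, ddz, x, z):
        fx = np.clip((x - x0) / ddx, 0.0, arr.shape[0] - 1.0 - 1e-12)
        fz = np.clip((z - z0) / ddz, 0.0, arr.shape[1] - 1.0 - 1e-12)
        i = fx.astype(int)
        j = fz.astype(int)
        tx = fx - i
        tz = fz - j
        return (
            arr[i, j] * (1 - tx) * (1 - tz)
            + arr[i + 1, j] * tx * (1 - tz)
            + arr[i, j + 1] * (1 - tx) * tz
            + arr[i + 1, j + 1] * tx * tz
        )

    x = pts[:, 0]
    z = pts[:, 1]
    u = bilin(fld.u, 0.0, 0.5 * dz, dx, dz, x, z)
    w = bilin(fld.w, 0.5 * dx, 0.0, dx, dz, x, z)
    return np.column_stack([u, w])


def surface_shear(
    fld: FlowField,
    domain: DomainSpec | None = None,
    fluid: FluidProperties | None = None,
    probe_offsets_um: tuple[float, float] = (1.5, 3.0),
) -> dict[int, list[SurfaceSample]]:
    """Shear magnitude sampled along each cell's analytic surface curve.

    At each sample point on the exposed profile, the velocity component
    tangential to the surface is probed at fixed normal offsets of
    ``probe_offsets_um`` (µm) into the fluid and differenced through the
    no-slip wall with a one-sided quadratic: τ = µ(4·u_t(δ) − u_t(2δ))/(2δ)
    for probes at δ and 2δ.  The offsets are physical lengths (not grid
    multiples) so the extraction is identical across grid refinements; they
    are floored at 1.25 grid spacings to stay clear of the rasterized
    boundary.  Returns cell index → samples ordered along the surface from
    the upstream contact line.
    """
    _require_converged(fld)
    domain = domain or fld.domain
    fluid = fluid or fld.fluid
    mu = fluid.dynamic_viscosity
    hgrid = max(fld.dx_cm, fld.dz_cm)
    d1 = max(probe_offsets_um[0] * 1e-4, 1.25 * hgrid)
    d2 = 2.0 * d1 if probe_offsets_um[1] * 1e-4 < 2.0 * d1 else probe_offsets_um[1] * 1e-4
    out: dict[int, list[SurfaceSample]] = {}
    for k, (x0_um, morph) in enumerate(domain.cells):
        # resample the profile at ~one grid spacing of arclength
        curve_um = _dense_profile(morph, hgrid * 1e4)
        xs = (curve_um[:, 0] + x0_um) * 1e-4
        zs = curve_um[:, 1] * 1e-4
        # tangent and outward normal by central differences along the curve
        tx = np.gradient(xs)
        tz = np.gradient(zs)
        norm = np.hypot(tx, tz)
        tx /= norm
        tz /= norm
        nxv, nzv = -tz, tx  # left normal; for a left-to-right curve it points up/out
        p1 = np.column_stack([xs + d1 * nxv, zs + d1 * nzv])
        p2 = np.column_stack([xs + d2 * nxv, zs + d2 * nzv])
        v1 = _interp_velocity(fld, p1)
        v2 = _interp_velocity(fld, p2)
        ut1 = v1[:, 0] * tx + v1[:, 1] * tz
        ut2 = v2[:, 0] * tx + v2[:, 1] * tz
        # quadratic through the wall: exact for u_t(n) = a n + b n²
        tau = np.abs(
            mu * (ut1 * d2**2 - ut2 * d1**2) / (d1 * d2 * (d2 - d1))
        )
        ds = np.empty_like(xs)
        seg = np.hypot(np.diff(xs), np.diff(zs))
        ds[0] = seg[0] / 2 if seg.size else 0.0
        ds[-1] = seg[-1] / 2 if seg.size else 0.0
        if seg.size > 1:
            ds[1:-1] = 0.5 * (seg[:-1] + seg[1:])
        out[k] = [
            SurfaceSample(float(x), float(z), float(t), float(s), "profile")
            for x, z, t, s in zip(xs, zs, tau, ds)
        ]
    return out


def _dense_profile(morph: CellMorphology, target_um: float) -> np.ndarray:
    """Profile polyline resampled to roughly uniform arclength spacing."""
    from .geometry import build_cell_profile

    fine = build_cell_profile(morph, n_points=2001)
    seg = np.hypot(np.diff(fine[:, 0]), np.diff(fine[:, 1]))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(16, int(np.ceil(arc[-1] / max(target_um, 1e-9))))
    s = np.linspace(0.0, arc[-1], n + 1)
    x = np.interp(s, arc, fine[:, 0])
    z = np.interp(s, arc, fine[:, 1])
    return np.column_stack([x, z])


def _peak_with_buffers(
    samples: Sequence[SurfaceSample], contact_exclusion: int, smooth_window: int
) -> float:
    """Peak shear after contact-line exclusion and staircase smoothing.

    Samples are ordered along x; the ``contact_exclusion`` samples nearest
    each floor contact line are dropped, then a centred moving average of
    ``smooth_window`` suppresses stair-step oscillation before taking the
    maximum.
    """
    taus = np.array([s.tau for s in samples])
    if contact_exclusion > 0 and taus.size > 2 * contact_exclusion + 1:
        taus = taus[contact_exclusion:-contact_exclusion]
    if smooth_window > 1 and taus.size >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        taus = np.convolve(taus, kernel, mode="valid")
    return float(taus.max())


def cell_shear_summary(
    fld: FlowField,
    domain: DomainSpec | None = None,
    fluid: FluidProperties | None = None,
    contact_exclusion: int = 2,
    smooth_window: int = 3,
) -> ShearReport:
    """Per-cell peak/mean shear and the τc/τw ratio for one solved field."""
    _require_converged(fld)
    domain = domain or fld.domain
    fluid = fluid or fld.fluid
    if not domain.cells:
        raise ValueError("domain has no cells; cell shear summary is undefined")
    samples = surface_shear(fld, domain, fluid)
    per_cell = []
    for k in sorted(samples):
        ss = samples[k]
        if not ss:
            raise SolverError(f"cell {k} has no exposed surface samples")
        peak = _peak_with_buffers(ss, contact_exclusion, smooth_window)
        lengths = np.array([s.face_length_cm for s in ss])
        taus = np.array([s.tau for s in ss])
        mean = float((taus * lengths).sum() / lengths.sum())
        per_cell.append(
            CellShear(
                index=k,
                role=domain.position_roles.get(k, "outer"),
                tau_c_peak=peak,
                tau_c_mean=min(mean, peak),
                n_samples=len(ss),
            )
        )
    morph = domain.cells[0][1]
    return ShearReport(
        per_cell=tuple(per_cell),
        tau_w_reference=wall_shear_stress(
            fld.q_requested_ul_hr, domain.channel, fluid
        ),
        q_ul_hr=fld.q_requested_ul_hr,
        morphology_label=morph.label,
        arrangement="single" if len(domain.cells) == 1 else "array",
    )


def _scaled_report(report: ShearReport, q_new: float) -> ShearReport:
    """Rescale a report to another flow rate using Stokes linearity."""
    s = q_new / report.q_ul_hr
    cells = tuple(
        replace(c, tau_c_peak=c.tau_c_peak * s, tau_c_mean=c.tau_c_mean * s)
        for c in report.per_cell
    )
    return replace(
        report,
        per_cell=cells,
        q_ul_hr=q_new,
        tau_w_reference=report.tau_w_reference * s,
    )


def geometry_spacing_um(
    morphology: CellMorphology,
    array: CellArraySpec,
    channel: ChannelSpec,
    base_um: float = 1.0,
) -> float:
    """Grid spacing resolving every geometric feature by >= 8 elements.

    Features: cell width, clearance above the cell, and (for arrays) the
    inter-cell gap.  Returns the base spacing unless a feature demands finer.
    """
    gap = array.gap_um if array.gap_um is not None else morphology.cell_width_um / 2.0
    feats = [
        morphology.cell_width_um,
        1e4 * channel.height - morphology.cell_height_um,
    ]
    if array.n_cells > 1:
        feats.append(gap)
    return min(base_um, min(feats) / 8.0)


def summary_table(
    morphologies: Iterable[CellMorphology],
    flows_ul_hr: Sequence[float],
    arrangements: Iterable[CellArraySpec] | None = None,
    channel: ChannelSpec | None = None,
    fluid: FluidProperties | None = None,
    config: SolverConfig | None = None,
    reuse_linearity: bool = True,
) -> pd.DataFrame:
    """Morphology × arrangement × flow-rate shear table (the summary figure).

    Rows are ordered by the given morphology order, then flow rate
    descending, one row per cell role.  In the Stokes regime all stresses
    are exactly linear in Q, so by default each geometry is solved once at
    the first flow rate and rescaled (``reuse_linearity=False`` forces a
    solve per flow rate).  Solver failures are annotated per row rather
    than aborting the whole table.
    """
    from .hydraulics import fabricated_channel

    channel = channel or fabricated_channel()
    fluid = fluid or culture_medium()
    config = config or SolverConfig()
    if arrangements is None:
        arrangements = [cell_array(1)]
    flows = sorted(flows_ul_hr, reverse=True)
    frames: list[pd.DataFrame] = []
    for morph in morphologies:
        for arr in arrangements:
            base_report: ShearReport | None = None
            for q in flows:
                try:
                    if (
                        reuse_linearity
                        and config.advection == "stokes"
                        and base_report is not None
                    ):
                        report = _scaled_report(base_report, q)
                    else:
                        spacing = geometry_spacing_um(
                            morph, arr, channel, config.grid_spacing_um
                        )
                        dom = build_domain(channel, arr, morph, resolution_um=spacing)
                        fld = solve_flow(
                            dom, q, fluid, replace(config, grid_spacing_um=spacing)
                        )
                        report = cell_shear_summary(fld, dom, fluid)
                        if base_report is None:
                            base_report = report
                    frames.append(report.to_frame())
                except (SolverError, ValueError) as exc:
                    frames.append(
                        pd.DataFrame(
                            [
                                {
                                    "morphology": morph.label,
                                    "arrangement": arr.arrangement,
                                    "role": "error",
                                    "cell_index": -1,
                                    "Q_uL_hr": q,
                                    "tau_w": np.nan,
                                    "tau_c_peak": np.nan,
                                    "tau_c_mean": np.nan,
                                    "ratio": np.nan,
                                    "error": str(exc),
                                }
                            ]
                        )
                    )
    table = pd.concat(frames, ignore_index=True)
    if "error" not in table.columns:
        table["error"] = ""
    else:
        table["error"] = table["error"].fillna("")
    return table
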