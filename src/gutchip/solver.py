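"""Steady incompressible low-Reynolds flow in the discretized channel window.

The solver discretizes the steady momentum and continuity equations

    µ ∇²u − ∇p − ρ (u·∇)u = 0,   ∇·u = 0

on a marker-and-cell (MAC) staggered grid: streamwise velocity u on vertical
cell faces, vertical velocity w on horizontal faces, pressure at cell
centres.  At perfusion rates relevant to epithelial culture the Reynolds
number is ~10⁻², so the default drops the advection term entirely (Stokes /
creeping flow), which makes the whole problem a single sparse linear solve
and makes every field exactly linear in the flow rate; an Oseen–Picard
iteration is retained as the ``navier_stokes`` option for fidelity checks.

Boundary conditions follow the physical chip: fully developed parabolic
inflow carrying exactly the requested flow rate, the identical profile at
the outflow plane (the window ends far from the obstacles, where the flow
has redeveloped), no-slip and impermeability on the floor, the top wall and
every cell surface, and the pressure gauge fixed so the outlet mean is zero.
Obstacles are rasterized stair-step onto the grid; flat wall segments that
fall on grid lines (the floor, the top wall, obstacle tops and sides aligned
with faces) are imposed to second order by ghost-node reflection, and
staircase corners to first order.  Repeated runs are bit-identical: there is
no randomness and the sparse direct solve is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .geometry import DomainSpec, empty_domain
from .hydraulics import (
    ChannelSpec,
    FluidProperties,
    culture_medium,
    fabricated_channel,
    reynolds_number,
    wall_shear_stress,
)


class SolverError(RuntimeError):
    """The flow solve failed (non-convergence or inconsistent setup)."""

    def __init__(self, message: str, residual: float | None = None) -> None:
        super().__init__(message)
        self.residual = residual


class ConfigError(ValueError):
    """Solver configuration inconsistent with the geometry."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the flow solve.

    Attributes
    ----------
    grid_spacing_um
        Target uniform grid spacing in µm.  The default 1 µm resolves the
        narrowest default cell (12 µm) by 12 elements.
    divergence_tolerance
        Maximum admissible relative continuity residual of the returned
        field (relative to the mean inlet speed over one cell).
    max_iterations
        Cap on Picard iterations in ``navier_stokes`` mode.
    advection
        ``stokes`` (default, inertialess) or ``navier_stokes``.
    picard_tol
        Relative velocity-update tolerance terminating the Picard loop.
    """

    grid_spacing_um: float = 1.0
    divergence_tolerance: float = 1e-8
    max_iterations: int = 50
    advection: Literal["stokes", "navier_stokes"] = "stokes"
    picard_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.grid_spacing_um <= 0.0:
            raise ConfigError(f"grid spacing must be > 0, got {self.grid_spacing_um}")
        if not (0.0 < self.divergence_tolerance <= 1e-6):
            raise ConfigError(
                "divergence tolerance must be in (0, 1e-6], got "
                f"{self.divergence_tolerance}"
            )
        if self.advection not in ("stokes", "navier_stokes"):
            raise ConfigError(f"unknown advection regime {self.advection!r}")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")


@dataclass(frozen=True)
class FlowField:
    """Discrete velocity–pressure solution on the staggered grid.

    ``u`` has shape (nx+1, nz) on vertical faces, ``w`` (nx, nz+1) on
    horizontal faces, ``p`` (nx, nz) at cell centres (NaN inside solids).
    Lengths are cm, velocities cm/s, pressure dyn/cm².
    """

    u: np.ndarray
    w: np.ndarray
    p: np.ndarray
    solid: np.ndarray
    dx_cm: float
    dz_cm: float
    domain: DomainSpec
    fluid: FluidProperties
    config: SolverConfig
    q_requested_ul_hr: float
    q_realized_ul_hr: float
    max_rel_divergence: float
    iterations: int = 1
    converged: bool = True

    @property
    def nx(self) -> int:
        return self.p.shape[0]

    @property
    def nz(self) -> int:
        return self.p.shape[1]

    def x_faces_cm(self) -> np.ndarray:
        return np.arange(self.nx + 1) * self.dx_cm

    def z_centers_cm(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz_cm

    def flux_per_column_cm2_s(self) -> np.ndarray:
        """2D flux ∫u dz through every vertical grid line (nx+1 values)."""
        return self.u.sum(axis=1) * self.dz_cm

    def to_hdf5(self, path: str) -> None:
        """Write the field to an HDF5 file (arrays + grid metadata)."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("u", data=self.u)
            fh.create_dataset("w", data=self.w)
            fh.create_dataset("p", data=self.p)
            fh.create_dataset("solid", data=self.solid)
            fh.attrs["dx_cm"] = self.dx_cm
            fh.attrs["dz_cm"] = self.dz_cm
            fh.attrs["q_requested_ul_hr"] = self.q_requested_ul_hr
            fh.attrs["q_realized_ul_hr"] = self.q_realized_ul_hr

    def to_vtk(self, path: str) -> None:
        """Write cell-centred velocity/pressure as a legacy-ASCII VTK grid."""
        nx, nz = self.nx, self.nz
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        wc = 0.5 * (self.w[:, :-1] + self.w[:, 1:])
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\ngutchip flow field\nASCII\n")
            fh.write("DATASET STRUCTURED_POINTS\n")
            fh.write(f"DIMENSIONS {nx} {nz} 1\n")
            fh.write(f"ORIGIN {0.5 * self.dx_cm} {0.5 * self.dz_cm} 0\n")
            fh.write(f"SPACING {self.dx_cm} {self.dz_cm} 1\n")
            fh.write(f"POINT_DATA {nx * nz}\n")
            fh.write("VECTORS velocity float\n")
            for j in range(nz):
                for i in range(nx):
                    fh.write(f"{uc[i, j]:.8e} {wc[i, j]:.8e} 0\n")
            fh.write("SCALARS pressure float 1\nLOOKUP_TABLE default\n")
            for j in range(nz):
                for i in range(nx):
                    v = self.p[i, j]
                    fh.write(f"{0.0 if np.isnan(v) else v:.8e}\n")


def _inlet_profile(nz: int, dz: float, h: float, q2d: float) -> np.ndarray:
    """Parabolic profile sampled at z-centres, rescaled so the discrete
    trapezoid-on-faces flux equals q2d exactly."""
    z = (np.arange(nz) + 0.5) * dz
    prof = 6.0 * (q2d / h) * (z / h) * (1.0 - z / h)
    discrete = prof.sum() * dz
    if discrete > 0.0:
        prof *= q2d / discrete
    return prof


def _check_resolution(domain: DomainSpec, config: SolverConfig) -> None:
    s = config.grid_spacing_um
    h_um = units.cm_to_um(domain.channel.height)
    scales = []
    xs = sorted((x0, m) for x0, m in domain.cells)
    for k, (x0, m) in enumerate(xs):
        scales.append(m.cell_width_um)
        scales.append(h_um - m.cell_height_um)
        if k + 1 < len(xs):
            gap = (xs[k + 1][0] - xs[k + 1][1].cell_width_um / 2.0) - (
                x0 + m.cell_width_um / 2.0
            )
            if gap > 0:
                scales.append(gap)
    if scales and min(scales) / s < 8.0:
        raise ConfigError(
            f"grid spacing {s} µm resolves the smallest geometric scale "
            f"({min(scales):.3g} µm) by fewer than 8 elements"
        )


def solve_flow(
    domain: DomainSpec,
    q_ul_hr: float,
    fluid: FluidProperties | None = None,
    config: SolverConfig | None = None,
) -> FlowField:
    """Solve the steady flow at volumetric rate ``q_ul_hr`` (µL/hr).

    Returns a :class:`FlowField` satisfying no-slip exactly on every wall
    node, carrying the requested flux through every cross section, and with
    a continuity residual below ``config.divergence_tolerance``.
    """
    fluid = fluid or culture_medium()
    config = config or SolverConfig()
    if q_ul_hr < 0.0:
        raise SolverError(f"flow rate must be >= 0, got {q_ul_hr}")
    _check_resolution(domain, config)
    re = reynolds_number(q_ul_hr, domain.channel, fluid)
    if config.advection == "stokes" and re >= 1.0:
        warnings.warn(
            f"Re = {re:.3g} >= 1: the Stokes (creeping flow) regime is "
            "questionable; consider advection='navier_stokes'",
            stacklevel=2,
        )

    q2d = units.ul_per_hr_to_cm3_s(q_ul_hr) / domain.channel.width  # cm²/s
    uvec, wvec, parts = _solve_linear(domain, q2d, fluid, config, None, None)
    iterations = 1
    if config.advection == "navier_stokes":
        for it in range(2, config.max_iterations + 1):
            u_prev, w_prev = uvec, wvec
            uvec, wvec, parts = _solve_linear(
                domain, q2d, fluid, config, u_prev, w_prev
            )
            scale = np.abs(u_prev).max() + 1e-300
            change = max(
                np.abs(uvec - u_prev).max(), np.abs(wvec - w_prev).max()
            ) / scale
            iterations = it
            if change < config.picard_tol:
                break
        else:
            raise SolverError(
                f"Picard iteration did not converge in {config.max_iterations} "
                f"iterations (last relative update {change:.3e})",
                residual=change,
            )
    return _package_field(domain, fluid, config, q_ul_hr, q2d, uvec, wvec, parts, iterations)


def _domain_elevation_um(domain: DomainSpec, x_um: float) -> float:
    """Obstacle surface elevation at streamwise position x (µm)."""
    e = 0.0
    for x0, morph in domain.cells:
        e = max(e, float(morph.elevation_um(x_um - x0)))
    return e


def _flank_x_um(domain: DomainSpec, near_x_um: float, z_um: float, side: str) -> float | None:
    """x-position (µm) of the cell flank nearest ``near_x_um`` at height z.

    ``side="right"`` returns the downstream (right) flank of the owning
    cell, ``side="left"`` its upstream flank; None if no cell owns the
    column.
    """
    k = domain.owner_of_column(near_x_um)
    if k is None:
        return None
    x0, morph = domain.cells[k]
    hw = morph.half_width_at(z_um)
    return x0 + hw if side == "right" else x0 - hw


def _solve_linear(domain, q2d, fluid, config, uc_prev, wc_prev):
    """Assemble and solve one (Stokes or Oseen-linearized) system.

    Viscous terms use a three-point stencil with per-link arm lengths: an
    interior link has arm = grid spacing, while a link cut by a wall carries
    the analytic wall distance (Shortley-Weller), so the no-slip boundary
    acts at its true sub-grid position rather than at the raster staircase.
    Returns full face arrays U (nx+1, nz), W (nx, nz+1) with boundary
    values filled in, plus a dict of grid/pressure data.
    """
    mu = fluid.dynamic_viscosity
    rho = fluid.density
    nx, nz, dx_um, dz_um = domain.grid_shape(config.grid_spacing_um)
    dx = units.um_to_cm(dx_um)
    dz = units.um_to_cm(dz_um)
    h = domain.channel.height
    solid = domain.solid_mask(config.grid_spacing_um)
    fl = ~solid

    # --- unknown numbering
    u_unknown = np.zeros((nx + 1, nz), dtype=bool)
    u_unknown[1:nx, :] = fl[:-1, :] & fl[1:, :]
    w_unknown = np.zeros((nx, nz + 1), dtype=bool)
    w_unknown[:, 1:nz] = fl[:, :-1] & fl[:, 1:]

    uid = -np.ones((nx + 1, nz), dtype=np.int64)
    nu = int(u_unknown.sum())
    uid[u_unknown] = np.arange(nu)
    wid = -np.ones((nx, nz + 1), dtype=np.int64)
    nw = int(w_unknown.sum())
    wid[w_unknown] = nu + np.arange(nw)
    pid = -np.ones((nx, nz), dtype=np.int64)
    npr = int(fl.sum())
    pid[fl] = nu + nw + np.arange(npr)
    ntot = nu + nw + npr

    uval = np.zeros((nx + 1, nz))
    uin = _inlet_profile(nz, dz, h, q2d)
    uval[0, :] = uin
    uval[nx, :] = uin
    wval = np.zeros((nx, nz + 1))

    Uc, Wc = (uc_prev, wc_prev) if uc_prev is not None else (None, None)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(ntot)

    def add_entries(r, c, v):
        rows.append(np.asarray(r))
        cols.append(np.asarray(c))
        vals.append(np.asarray(v, dtype=float))

    def axis_terms(row, rhs, am, ap, m_id, p_id, m_val, p_val, conv):
        """Viscous + advective contributions of one axis (arms am/ap).

        m_id/p_id: neighbor unknown ids (-1 if not an unknown); m_val/p_val:
        Dirichlet values used where the id is -1 (walls contribute 0).
        ``conv``: ρ·(convecting velocity) at the node, or None for Stokes.
        Returns the diagonal contribution.
        """
        denom = am + ap
        c_m = 2.0 * mu / (am * denom)
        c_p = 2.0 * mu / (ap * denom)
        diag = -2.0 * mu / (am * ap)
        if conv is not None:
            c_m = c_m + conv * ap / (am * denom)
            c_p = c_p - conv * am / (ap * denom)
            diag = diag - conv * (ap - am) / (am * ap)
        for cc, idn, val in ((c_m, m_id, m_val), (c_p, p_id, p_val)):
            unk = idn >= 0
            add_entries(row[unk], idn[unk], cc[unk])
            kn = ~unk & (val != 0.0)
            np.subtract.at(rhs, row[kn], cc[kn] * val[kn])
        return diag

    def wall_arms_u(I, J, blocked, axis):
        """Arm lengths for u-node links cut by a wall (cm)."""
        if axis == "z-":
            arm = np.full(I.shape, dz)
            floor = blocked & (J == 0)
            arm[floor] = dz / 2.0
            obst = np.nonzero(blocked & (J > 0))[0]
            for t in obst:
                z_node = (J[t] + 0.5) * dz
                e = units.um_to_cm(
                    _domain_elevation_um(domain, units.cm_to_um(I[t] * dx))
                )
                arm[t] = np.clip(z_node - e, 0.05 * dz, 1.9 * dz)
            return arm
        if axis == "z+":
            arm = np.full(I.shape, dz)
            arm[blocked] = dz / 2.0  # only the ceiling blocks from above
            return arm
        arm = np.full(I.shape, dx)
        for t in np.nonzero(blocked)[0]:
            z_um = units.cm_to_um((J[t] + 0.5) * dz)
            if axis == "x-":
                xw = _flank_x_um(domain, units.cm_to_um((I[t] - 1) * dx), z_um, "right")
                gap = I[t] * dx - units.um_to_cm(xw) if xw is not None else dx
            else:
                xw = _flank_x_um(domain, units.cm_to_um((I[t] + 1) * dx), z_um, "left")
                gap = units.um_to_cm(xw) - I[t] * dx if xw is not None else dx
            arm[t] = np.clip(gap, 0.05 * dx, 1.9 * dx)
        return arm

    # ---------------- momentum-x rows -----------------------------------
    I, J = np.nonzero(u_unknown)
    row = uid[I, J]
    n = I.size
    zeros = np.zeros(n)

    if Uc is not None:
        conv_u = rho * Uc[I, J]
        conv_w = rho * 0.25 * (Wc[I - 1, J] + Wc[I - 1, J + 1] + Wc[I, J] + Wc[I, J + 1])
    else:
        conv_u = conv_w = None

    # x-axis: neighbors are u-faces at i-1 / i+1 (inlet/outlet carry values)
    m_id = uid[I - 1, J]
    p_id = uid[I + 1, J]
    m_val = np.where(I - 1 == 0, uval[0, J], 0.0)
    p_val = np.where(I + 1 == nx, uval[nx, J], 0.0)
    m_blocked = (m_id < 0) & (I - 1 > 0)
    p_blocked = (p_id < 0) & (I + 1 < nx)
    am = wall_arms_u(I, J, m_blocked, "x-")
    ap = wall_arms_u(I, J, p_blocked, "x+")
    diag = axis_terms(row, rhs, am, ap, m_id, p_id, m_val, p_val, conv_u)

    # z-axis: floor/ceiling at half spacing, obstacle tops at analytic height
    m_id = np.where(J - 1 >= 0, uid[I, np.maximum(J - 1, 0)], -1)
    p_id = np.where(J + 1 <= nz - 1, uid[I, np.minimum(J + 1, nz - 1)], -1)
    m_blocked = m_id < 0
    p_blocked = p_id < 0
    ab = wall_arms_u(I, J, m_blocked, "z-")
    at = wall_arms_u(I, J, p_blocked, "z+")
    diag = diag + axis_terms(row, rhs, ab, at, m_id, p_id, zeros, zeros, conv_w)

    add_entries(row, row, diag)
    add_entries(row, pid[I, J], np.full(n, -1.0 / dx))
    add_entries(row, pid[I - 1, J], np.full(n, 1.0 / dx))

    # ---------------- momentum-z rows -----------------------------------
    I, J = np.nonzero(w_unknown)
    row = wid[I, J]
    n = I.size
    zeros = np.zeros(n)

    if Uc is not None:
        conv_u = rho * 0.25 * (Uc[I, J - 1] + Uc[I, J] + Uc[I + 1, J - 1] + Uc[I + 1, J])
        conv_w = rho * Wc[I, J]
    else:
        conv_u = conv_w = None

    def wall_arms_w(I, J, blocked, axis):
        if axis == "z-":
            arm = np.full(I.shape, dz)
            obst = np.nonzero(blocked & (J - 1 > 0))[0]
            for t in obst:
                z_node = J[t] * dz
                e = units.um_to_cm(
                    _domain_elevation_um(domain, units.cm_to_um((I[t] + 0.5) * dx))
                )
                arm[t] = np.clip(z_node - e, 0.05 * dz, 1.9 * dz)
            return arm  # J-1 == 0: floor node at exactly one arm
        if axis == "z+":
            return np.full(I.shape, dz)  # ceiling node exact
        arm = np.full(I.shape, dx)
        plane = blocked & ((I == 0) if axis == "x-" else (I == nx - 1))
        arm[plane] = dx / 2.0
        for t in np.nonzero(blocked & ~plane)[0]:
            z_um = units.cm_to_um(J[t] * dz)
            x_node = (I[t] + 0.5) * dx
            if axis == "x-":
                xw = _flank_x_um(domain, units.cm_to_um((I[t] - 0.5) * dx), z_um, "right")
                gap = x_node - units.um_to_cm(xw) if xw is not None else dx
            else:
                xw = _flank_x_um(domain, units.cm_to_um((I[t] + 1.5) * dx), z_um, "left")
                gap = units.um_to_cm(xw) - x_node if xw is not None else dx
            arm[t] = np.clip(gap, 0.05 * dx, 1.9 * dx)
        return arm

    m_id = np.where(I - 1 >= 0, wid[np.maximum(I - 1, 0), J], -1)
    p_id = np.where(I + 1 <= nx - 1, wid[np.minimum(I + 1, nx - 1), J], -1)
    am = wall_arms_w(I, J, m_id < 0, "x-")
    ap = wall_arms_w(I, J, p_id < 0, "x+")
    diag = axis_terms(row, rhs, am, ap, m_id, p_id, zeros, zeros, conv_u)

    m_id = wid[I, J - 1]
    p_id = wid[I, J + 1]
    ab = wall_arms_w(I, J, m_id < 0, "z-")
    at = wall_arms_w(I, J, p_id < 0, "z+")
    diag = diag + axis_terms(row, rhs, ab, at, m_id, p_id, zeros, zeros, conv_w)

    add_entries(row, row, diag)
    add_entries(row, pid[I, J], np.full(n, -1.0 / dz))
    add_entries(row, pid[I, J - 1], np.full(n, 1.0 / dz))

    # ---------------- continuity rows ------------------------------------
    I, J = np.nonzero(fl)
    row = pid[I, J]
    # anchor cell (outlet-top fluid cell): its row becomes p = 0
    anchor_flat = np.lexsort((J, I))[-1]
    anchor_row = row[anchor_flat]
    keep = row != anchor_row

    def cont_face(grid_id, grid_val, ni, nj, coef):
        idn = grid_id[ni, nj]
        unknown = (idn >= 0) & keep
        known = (idn < 0) & keep
        add_entries(row[unknown], idn[unknown], np.full(int(unknown.sum()), coef))
        np.subtract.at(rhs, row[known], coef * grid_val[ni[known], nj[known]])

    cont_face(uid, uval, I + 1, J, 1.0 / dx)
    cont_face(uid, uval, I, J, -1.0 / dx)
    cont_face(wid, wval, I, J + 1, 1.0 / dz)
    cont_face(wid, wval, I, J, -1.0 / dz)
    add_entries(
        np.array([anchor_row]),
        np.array([pid[I[anchor_flat], J[anchor_flat]]]),
        np.array([1.0]),
    )
    rhs[anchor_row] = 0.0

    # ---------------- scale rows and solve --------------------------------
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ntot, ntot),
    ).tocsr()
    rowscale = np.ones(ntot)
    rowscale[: nu + nw] = dx**2 / mu
    rowscale[nu + nw :] = dx
    rowscale[anchor_row] = 1.0
    A = sp.diags(rowscale) @ A
    rhs = rowscale * rhs

    sol = spla.spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(sol)):
        raise SolverError("sparse solve returned non-finite values")

    U = uval.copy()
    U[u_unknown] = sol[uid[u_unknown]]
    W = wval.copy()
    W[w_unknown] = sol[wid[w_unknown]]
    P = np.full((nx, nz), np.nan)
    P[fl] = sol[pid[fl]]
    # gauge: zero mean pressure over the outlet column
    P[fl] -= np.nanmean(P[nx - 1, :])

    parts = {
        "P": P,
        "solid": solid,
        "dx": dx,
        "dz": dz,
        "fl": fl,
    }
    return U, W, parts


def _package_field(domain, fluid, config, q_ul_hr, q2d, U, W, parts, iterations):
    dx, dz = parts["dx"], parts["dz"]
    fl = parts["fl"]
    div = (U[1:, :] - U[:-1, :]) / dx + (W[:, 1:] - W[:, :-1]) / dz
    u_char = q2d / domain.channel.height
    if u_char == 0.0:  # degenerate no-flow solve: field is identically zero
        u_char = 1.0
    max_rel_div = float(np.abs(div[fl]).max() * min(dx, dz) / u_char)
    if max_rel_div > config.divergence_tolerance:
        raise SolverError(
            f"continuity residual {max_rel_div:.3e} exceeds tolerance "
            f"{config.divergence_tolerance:.1e}",
            residual=max_rel_div,
        )
    flux = U.sum(axis=1) * dz  # per column, cm²/s
    q_real = float(np.mean(flux)) * domain.channel.width
    q_real_ul = units.cm3_s_to_ul_per_hr(q_real)
    if abs(q_real_ul - q_ul_hr) > 1e-3 * max(q_ul_hr, 1e-12):
        raise SolverError(
            f"realized flow rate {q_real_ul:.6g} µL/hr deviates from requested "
            f"{q_ul_hr:.6g} by more than 0.1%"
        )
    return FlowField(
        u=U,
        w=W,
        p=parts["P"],
        solid=parts["solid"],
        dx_cm=dx,
        dz_cm=dz,
        domain=domain,
        fluid=fluid,
        config=config,
        q_requested_ul_hr=q_ul_hr,
        q_realized_ul_hr=q_real_ul,
        max_rel_divergence=max_rel_div,
        iterations=iterations,
        converged=True,
    )


def floor_shear_profile(field: FlowField, fluid: FluidProperties) -> np.ndarray:
    """Shear stress µ ∂u/∂z on the (uncovered) channel floor per u-face.

    Second-order one-sided difference through the wall value 0; returns NaN
    where the floor is covered by an obstacle footprint.
    """
    mu = fluid.dynamic_viscosity
    dz = field.dz_cm
    u1 = field.u[:, 0]
    u2 = field.u[:, 1]
    tau = mu * (9.0 * u1 - u2) / (3.0 * dz)
    covered = np.zeros(field.nx + 1, dtype=bool)
    covered[1:-1] = field.solid[:-1, 0] | field.solid[1:, 0]
    tau = np.where(covered, np.nan, tau)
    return np.abs(tau)


def top_wall_shear_profile(field: FlowField, fluid: FluidProperties) -> np.ndarray:
    """Shear stress magnitude on the top wall per u-face."""
    mu = fluid.dynamic_viscosity
    dz = field.dz_cm
    u1 = field.u[:, -1]
    u2 = field.u[:, -2]
    return np.abs(mu * (9.0 * u1 - u2) / (3.0 * dz))


@dataclass(frozen=True)
class ValidationReport:
    """Grid-refinement comparison of the solver against plane Poiseuille."""

    spacings_um: tuple[float, ...]
    l2_velocity_errors: tuple[float, ...]
    floor_shear_errors: tuple[float, ...]
    monotone: bool
    passed: bool


def validate_against_analytic(
    config: SolverConfig | None = None,
    channel: ChannelSpec | None = None,
    fluid: FluidProperties | None = None,
    q_ul_hr: float = 29.0,
    spacings_um: tuple[float, ...] | None = None,
) -> ValidationReport:
    """Empty-channel refinement study against the plane-Poiseuille closed form.

    Solves the obstacle-free window at three (or more) grid spacings,
    defaulting to h/10, h/20, h/40, and reports the relative L2 error of the
    streamwise velocity against the exact parabola and the relative error of
    the mid-window floor shear against 6µQ/(wh²).  Both must decrease
    monotonically under refinement for the report to pass.
    """
    config = config or SolverConfig()
    channel = channel or fabricated_channel()
    fluid = fluid or culture_medium()
    h_um = units.cm_to_um(channel.height)
    if spacings_um is None:
        spacings_um = (h_um / 10.0, h_um / 20.0, h_um / 40.0)
    tau_ref = wall_shear_stress(q_ul_hr, channel, fluid)
    q2d = units.ul_per_hr_to_cm3_s(q_ul_hr) / channel.width

    l2_errors = []
    shear_errors = []
    for s in spacings_um:
        dom = empty_domain(channel, resolution_um=s)
        fld = solve_flow(dom, q_ul_hr, fluid, replace(config, grid_spacing_um=s))
        z = fld.z_centers_cm()
        h = channel.height
        u_exact = 6.0 * (q2d / h) * (z / h) * (1.0 - z / h)
        err = np.sqrt(np.mean((fld.u - u_exact[None, :]) ** 2))
        l2_errors.append(float(err / np.sqrt(np.mean(u_exact**2))))
        tau = floor_shear_profile(fld, fluid)
        mid = tau[fld.nx // 2]
        shear_errors.append(float(abs(mid - tau_ref) / tau_ref))
    mono = all(a > b for a, b in zip(l2_errors, l2_errors[1:]))
    passed = mono and l2_errors[-1] < 0.01 and shear_errors[-1] < 0.01
    return ValidationReport(
        spacings_um=tuple(spacings_um),
        l2_velocity_errors=tuple(l2_errors),
        floor_shear_errors=tuple(shear_errors),
        monotone=mono,
        passed=passed,
    )
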