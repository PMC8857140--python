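"""Two-dimensional flow-cell model.

The flow cell is a rectangular chamber (default 3 mm × 3 mm) with a
parabolic inlet on the left, an outlet on the right, and no-slip walls top
and bottom.  Biofilms occupy the φ < 0 region of a level-set field on a
fixed cell-centered Cartesian grid.  One coupled step solves, in order:

1. Stokes-approximated fluid flow (pressure Laplace + two velocity Poisson
   solves), re-solved only when the interface has moved;
2. transient advection–diffusion of extracellular glutamate and potassium on
   the whole grid, with harmonic-mean face diffusivities enforcing flux and
   concentration continuity across the biofilm interface, implicit in time;
3. the cellular reaction dynamics (identical pointwise terms to the 1D
   model) inside the biofilm, with upwind advection by the growth velocity;
4. a growth potential ∇²Ω = δ_grow·M_grow·G_in (Ω = 0 on the interface),
   whose gradient is the biomass expansion velocity, and a level-set
   advance with normal speed F = ∇Ω·n.

Cell indexing is ``field[j, i]`` with x = (i+0.5)h, y = (j+0.5)h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import model1d as m1
from .levelset import (advance_interface, extend_to_everywhere,
                       interface_area, reinitialize,
                       signed_distance_from_mask)
from .params import ParameterSet

__all__ = [
    "Grid2D", "FluidField", "State2D", "ShapeSpec", "Trace2D",
    "solve_pressure_velocity", "fluid_transport_steady",
    "interface_coupled_diffusion_step", "growth_potential_velocity",
    "run_2d", "GeometryError",
]

#: Printed 2D initial condition (V differs from the 1D value).
DEFAULT_INIT_2D = dict(m1.DEFAULT_INIT, V=-160.0)

CELL_FIELDS = ("G_in", "K_in", "K_acclimated", "V", "n", "T", "A")


class GeometryError(ValueError):
    """A biofilm shape conflicts with the flow-cell geometry."""


class SolverError(RuntimeError):
    """A linear solve failed or left an unacceptable residual."""


@dataclass(frozen=True)
class Grid2D:
    """Cell-centered square-cell grid over the flow cell."""

    Lx: float = 3.0
    Ly: float = 3.0
    h: float = 0.025

    @property
    def nx(self) -> int:
        return int(round(self.Lx / self.h))

    @property
    def ny(self) -> int:
        return int(round(self.Ly / self.h))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) + 0.5) * self.h
        y = (np.arange(self.ny) + 0.5) * self.h
        return np.meshgrid(x, y)


@dataclass
class FluidField:
    u: np.ndarray
    v: np.ndarray
    P: np.ndarray


@dataclass
class ShapeSpec:
    """A biofilm footprint: a boolean mask on the grid (mm-per-pixel = h).

    Construct directly from a mask, from :mod:`biofilmosc.shapes`
    generators, or from a polygon via :func:`ShapeSpec.from_polygon`.
    """

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise GeometryError("biofilm shape is empty")

    @classmethod
    def from_polygon(cls, vertices_mm, grid: Grid2D) -> "ShapeSpec":
        from matplotlib.path import Path
        X, Y = grid.cell_centers()
        pts = np.column_stack([X.ravel(), Y.ravel()])
        inside = Path(np.asarray(vertices_mm, dtype=float)).contains_points(
            pts)
        return cls(mask=inside.reshape(grid.shape))

    def validate(self, grid: Grid2D) -> None:
        if self.mask.shape != grid.shape:
            raise GeometryError("mask shape does not match the grid")
        if self.mask[:, 0].any() or self.mask[:, -1].any():
            raise GeometryError("biofilm touches the inlet or outlet")


@dataclass
class State2D:
    """Cellular fields (defined where φ<0), concentrations (everywhere),
    level set, and the fluid solution."""

    grid: Grid2D
    phi: np.ndarray
    G: np.ndarray
    K: np.ndarray
    cell: dict                      # name -> 2D array, valid where inside
    fluid: FluidField | None = None
    Omega: np.ndarray | None = None

    @property
    def inside(self) -> np.ndarray:
        return self.phi < 0.0

    @property
    def area_mm2(self) -> float:
        return interface_area(self.phi, self.grid.h)


# --------------------------------------------------------------------------
# sparse assembly helpers
# --------------------------------------------------------------------------

_DIRS = ((0, 1), (0, -1), (1, 0), (-1, 0))  # E, W, N, S as (dj, di)


def _neighbor_views(a: np.ndarray, dj: int, di: int):
    """(center_slice, neighbor_slice) index tuples for direction (dj, di)."""
    sj_c = slice(None) if dj == 0 else (slice(0, -1) if dj > 0 else
                                        slice(1, None))
    sj_n = slice(None) if dj == 0 else (slice(1, None) if dj > 0 else
                                        slice(0, -1))
    si_c = slice(None) if di == 0 else (slice(0, -1) if di > 0 else
                                        slice(1, None))
    si_n = slice(None) if di == 0 else (slice(1, None) if di > 0 else
                                        slice(0, -1))
    return (sj_c, si_c), (sj_n, si_n)


class _Coo:
    """Incremental COO triplet collector."""

    def __init__(self):
        self.r, self.c, self.v = [], [], []

    def add(self, rows, cols, vals):
        r = np.asarray(rows).ravel()
        self.r.append(r)
        self.c.append(np.asarray(cols).ravel())
        v = np.asarray(vals, dtype=float).ravel()
        if v.size == 1:
            v = np.broadcast_to(v, r.shape)
        self.v.append(np.ascontiguousarray(v, dtype=float))

    def matrix(self, n):
        return sp.csr_matrix(
            (np.concatenate(self.v),
             (np.concatenate(self.r), np.concatenate(self.c))),
            shape=(n, n))


def _edge_cells(mask_u, side):
    """Boolean array: unknown cells on a domain edge ('W','E','S','N')."""
    out = np.zeros_like(mask_u)
    if side == "W":
        out[:, 0] = mask_u[:, 0]
    elif side == "E":
        out[:, -1] = mask_u[:, -1]
    elif side == "S":
        out[0, :] = mask_u[0, :]
    elif side == "N":
        out[-1, :] = mask_u[-1, :]
    return out


def solve_pressure_velocity(grid: Grid2D, phi: np.ndarray,
                            p: ParameterSet,
                            residual_tol: float = 1e-8) -> FluidField:
    """Stokes-approximation fluid solve: ∇²P = 0, then μ∇²u = ∂P/∂x and
    μ∇²v = ∂P/∂y.

    Boundary conditions: no-slip/no-penetration (u = v = 0, ∇P·n = 0) on
    the walls and on the biofilm interface; parabolic inlet profile with
    centerline speed u0 and v = 0; outlet ∂u/∂x = 0, v = 0, P = 0.  The
    inlet pressure gradient is set to the Poiseuille-consistent value
    −2·mu·u0/H², which makes the empty-channel solution exact.
    """
    h, ny, nx = grid.h, grid.ny, grid.nx
    fluid = phi >= 0.0
    if not fluid[:, 0].all() or not fluid[:, -1].all():
        raise GeometryError("biofilm occludes the inlet or outlet column")
    n = int(fluid.sum())
    ids = np.full(grid.shape, -1, dtype=int)
    ids[fluid] = np.arange(n)
    H = grid.Ly / 2.0
    yc = grid.Ly / 2.0
    y = (np.arange(ny) + 0.5) * h
    u_in_profile = p.u0 * (1.0 - ((y - yc) / H) ** 2)
    gP = -2.0 * p.mu * p.u0 / H**2   # dP/dx at the inlet

    invh2 = 1.0 / h**2

    # ---- pressure: Laplacian(P) = 0 --------------------------------------
    A = _Coo()
    b = np.zeros(n)
    diag = np.zeros(n)
    for dj, di in _DIRS:
        (cc, nn) = _neighbor_views(ids, dj, di)
        mC = fluid[cc] & fluid[nn]
        A.add(ids[cc][mC], ids[nn][mC], invh2)
        diag[ids[cc][mC]] -= invh2
        # faces to biofilm cells: Neumann zero (drop)
    # inlet: Neumann with specified gradient
    w_edge = _edge_cells(fluid, "W")
    b[ids[w_edge]] += gP / h
    # outlet: Dirichlet P=0 at face
    e_edge = _edge_cells(fluid, "E")
    diag[ids[e_edge]] -= 2.0 * invh2
    A.add(np.arange(n), np.arange(n), 0.0)
    M = A.matrix(n) + sp.diags(diag)
    P_vec = spla.spsolve(M.tocsc(), b)
    _check_residual(M, P_vec, b, residual_tol, "pressure")
    P = np.zeros(grid.shape)
    P[fluid] = P_vec

    # pressure gradients at fluid cells (one-sided near blocked neighbors)
    dPdx = _masked_gradient(P, fluid, h, axis=1)
    dPdy = _masked_gradient(P, fluid, h, axis=0)

    # ---- velocities ------------------------------------------------------
    def _velocity(rhs_grad, inlet_vals, outlet_neumann):
        A = _Coo()
        diag = np.zeros(n)
        b = rhs_grad[fluid] / p.mu
        for dj, di in _DIRS:
            (cc, nn) = _neighbor_views(ids, dj, di)
            mU = fluid[cc] & fluid[nn]
            A.add(ids[cc][mU], ids[nn][mU], invh2)
            diag[ids[cc][mU]] -= invh2
            mB = fluid[cc] & ~fluid[nn]      # no-slip at biofilm face
            diag[ids[cc][mB]] -= 2.0 * invh2
        for side in ("S", "N"):              # walls: Dirichlet 0
            eg = _edge_cells(fluid, side)
            diag[ids[eg]] -= 2.0 * invh2
        wg = _edge_cells(fluid, "W")         # inlet: Dirichlet profile
        diag[ids[wg]] -= 2.0 * invh2
        b[ids[wg]] -= 2.0 * invh2 * inlet_vals[wg.any(axis=1)]
        if not outlet_neumann:               # outlet: Dirichlet 0
            eg = _edge_cells(fluid, "E")
            diag[ids[eg]] -= 2.0 * invh2
        A.add(np.arange(n), np.arange(n), 0.0)
        M = A.matrix(n) + sp.diags(diag)
        sol = spla.spsolve(M.tocsc(), b)
        _check_residual(M, sol, b, residual_tol, "velocity")
        out = np.zeros(grid.shape)
        out[fluid] = sol
        return out

    u = _velocity(dPdx, u_in_profile, outlet_neumann=True)
    v = _velocity(dPdy, np.zeros(ny), outlet_neumann=False)
    return FluidField(u=u, v=v, P=P)


def _check_residual(M, x, b, tol, label):
    r = np.linalg.norm(M @ x - b)
    scale = max(np.linalg.norm(b), 1e-30)
    if not np.isfinite(r) or (scale > 1e-14 and r / scale > tol):
        raise SolverError(
            f"{label} solve residual {r / scale:.3g} above {tol:.3g}")


def _masked_gradient(f, mask, h, axis):
    """Central gradient where both neighbors are in the mask; one-sided at
    mask edges; zero where isolated."""
    if axis == 0:
        return _masked_gradient(f.T, mask.T, h, axis=1).T
    fm = np.where(mask, f, np.nan)
    ctr = np.full_like(f, np.nan)
    fwd = np.full_like(f, np.nan)
    bwd = np.full_like(f, np.nan)
    ctr[:, 1:-1] = (fm[:, 2:] - fm[:, :-2]) / (2 * h)
    fwd[:, :-1] = (fm[:, 1:] - fm[:, :-1]) / h
    bwd[:, 1:] = (fm[:, 1:] - fm[:, :-1]) / h
    g = np.where(np.isfinite(ctr), ctr,
                 np.where(np.isfinite(fwd), fwd,
                          np.where(np.isfinite(bwd), bwd, 0.0)))
    g[~mask] = 0.0
    return g


def fluid_transport_steady(grid: Grid2D, fluid_field: FluidField,
                           phi: np.ndarray, p: ParameterSet,
                           species: str = "G",
                           interface_values: np.ndarray | None = None
                           ) -> np.ndarray:
    """Steady advection–diffusion of one species in the fluid region.

    Solves D∇²c − ∇·(c u) = 0 with Dirichlet inlet (G0 or K0), no-flux
    walls, zero-diffusive-flux outlet (advective outflow), and — when the
    biofilm region is non-empty — Dirichlet values on interface faces taken
    from ``interface_values`` (the biofilm-side concentration field).
    Upwind advection gives a discrete maximum principle.
    """
    h = grid.h
    fluid = phi >= 0.0
    D = (p.D_G_fl if species == "G" else p.D_K_fl)
    c0 = (p.G0 if species == "G" else p.K0)
    n = int(fluid.sum())
    ids = np.full(grid.shape, -1, dtype=int)
    ids[fluid] = np.arange(n)
    invh2 = 1.0 / h**2
    u, v = fluid_field.u, fluid_field.v

    # Advection uses the advective (non-divergence) upwind form u·∇c: the
    # Stokes-approximated velocity field is not discretely divergence-free,
    # and the conservative form would create spurious sources/sinks where
    # the discrete divergence is non-zero; the two forms coincide for
    # incompressible flow.
    A = _Coo()
    diag = np.zeros(n)
    b = np.zeros(n)
    for dj, di in _DIRS:
        (cc, nn) = _neighbor_views(ids, dj, di)
        vel_field = u if dj == 0 else v
        sign = 1.0 if (di + dj) > 0 else -1.0   # outward normal component
        # upwind: this direction supplies c when the flow enters from it,
        # i.e. when the outward-projected cell velocity is negative
        vc = vel_field[cc] * sign
        upw = np.maximum(-vc, 0.0) / h
        mU = fluid[cc] & fluid[nn]
        idc, idn = ids[cc][mU], ids[nn][mU]
        # diffusion
        A.add(idc, idn, invh2 * D)
        diag[idc] -= invh2 * D
        # advective inflow from the upwind neighbor
        A.add(idc, idn, upw[mU])
        diag[idc] -= upw[mU]
        # faces to biofilm cells: Dirichlet interface value
        mB = fluid[cc] & ~fluid[nn]
        if mB.any():
            if interface_values is None:
                raise SolverError(
                    "interface_values required when a biofilm is present")
            idc = ids[cc][mB]
            cval = interface_values[nn][mB]
            diag[idc] -= 2.0 * invh2 * D + upw[mB]
            b[idc] -= (2.0 * invh2 * D + upw[mB]) * cval
    # inlet: Dirichlet c0 (diffusive + upwind inflow)
    wg = _edge_cells(fluid, "W")
    idw = ids[wg]
    uin = np.maximum(u[wg], 0.0) / h
    diag[idw] -= 2.0 * invh2 * D + uin
    b[idw] -= (2.0 * invh2 * D + uin) * c0
    # outlet: zero-gradient (upwind value is the cell itself: no terms)
    A.add(np.arange(n), np.arange(n), 0.0)
    M = A.matrix(n) + sp.diags(diag)
    sol = spla.spsolve(M.tocsc(), b)
    _check_residual(M, sol, b, 1e-8, "steady transport")
    out = np.zeros(grid.shape)
    out[fluid] = sol
    return out


class TransportOperator:
    """Implicit transient advection–diffusion operator on the full grid.

    Faces use harmonic-mean diffusivity between the biofilm and fluid
    values, which enforces flux continuity at the interface in the
    finite-volume sense; advection uses the (implicit, upwind) fluid
    velocity.  ``closed=True`` shuts every boundary exchange off (used for
    conservation checks).
    """

    def __init__(self, grid: Grid2D, inside: np.ndarray,
                 fluid_field: FluidField | None, D_in: float, D_out: float,
                 c_inlet: float, dt: float, closed: bool = False):
        h = grid.h
        ny, nx = grid.shape
        n = nx * ny
        ids = np.arange(n).reshape(grid.shape)
        Dmap = np.where(inside, D_in, D_out)
        u = fluid_field.u if fluid_field is not None else np.zeros(grid.shape)
        v = fluid_field.v if fluid_field is not None else np.zeros(grid.shape)
        invh2 = 1.0 / h**2

        # advective (u·∇c) upwind form — see fluid_transport_steady for why
        A = _Coo()
        diag = np.zeros(n)
        bconst = np.zeros(n)
        for dj, di in _DIRS:
            (cc, nn) = _neighbor_views(ids, dj, di)
            Dface = 2.0 * Dmap[cc] * Dmap[nn] / (Dmap[cc] + Dmap[nn])
            idc, idn = ids[cc], ids[nn]
            A.add(idc, idn, (invh2 * Dface).ravel())
            diag[idc.ravel()] -= (invh2 * Dface).ravel()
            vel_field = u if dj == 0 else v
            sign = 1.0 if (di + dj) > 0 else -1.0
            upw = np.maximum(-(vel_field[cc] * sign), 0.0) / h
            A.add(idc, idn, upw.ravel())
            diag[idc.ravel()] -= upw.ravel()
        if not closed:
            wg = np.zeros(grid.shape, dtype=bool)
            wg[:, 0] = True
            idw = ids[wg]
            uin = np.maximum(u[wg], 0.0) / h
            diag[idw] -= 2.0 * invh2 * D_out + uin
            bconst[idw] += (2.0 * invh2 * D_out + uin) * c_inlet
        A.add(np.arange(n), np.arange(n), 0.0)
        L = A.matrix(n) + sp.diags(diag)
        self.bconst = bconst
        self.dt = dt
        self.shape = grid.shape
        self.lu = spla.splu((sp.identity(n) - dt * L).tocsc())

    def step(self, c: np.ndarray, source: np.ndarray | None = None
             ) -> np.ndarray:
        rhs = c.ravel() + self.dt * self.bconst
        if source is not None:
            rhs = rhs + self.dt * source.ravel()
        out = self.lu.solve(rhs)
        if not np.all(np.isfinite(out)):
            raise SolverError("transport solve produced non-finite values")
        return out.reshape(self.shape)


def interface_coupled_diffusion_step(
        state: State2D, p: ParameterSet, dt: float,
        closed: bool = False,
        sources: tuple[np.ndarray, np.ndarray] | None = None) -> None:
    """Advance G and K by one implicit transport step (in place)."""
    ops = _transport_ops(state, p, dt, closed)
    srcG = sources[0] if sources else None
    srcK = sources[1] if sources else None
    state.G = ops[0].step(state.G, srcG)
    state.K = ops[1].step(state.K, srcK)


def _transport_ops(state: State2D, p: ParameterSet, dt: float,
                   closed: bool = False):
    return (TransportOperator(state.grid, state.inside, state.fluid,
                              p.D_G, p.D_G_fl, p.G0, dt, closed),
            TransportOperator(state.grid, state.inside, state.fluid,
                              p.D_K, p.D_K_fl, p.K0, dt, closed))


def growth_potential_velocity(state: State2D, p: ParameterSet,
                              variant: m1.VariantSpec = m1.FULL,
                              literal_form: bool = False):
    """(Ω, U = ∇Ω, interface normal speed F extended everywhere).

    Solves ∇²Ω = δ_grow·M_grow·G_in inside the biofilm with Ω = 0 on the
    interface and ∇Ω·n = 0 on flow-cell walls the biofilm touches.  In the
    slab limit this reproduces the 1D growth law dL/dt = δ_grow∫G_in·M dx.
    ``literal_form`` instead evaluates Ω = δ_grow·∇²(M_grow·G_in)
    pointwise (the typeset variant, retained for comparison).
    """
    grid, inside = state.grid, state.inside
    h = grid.h
    if not inside.any():
        raise GeometryError("biofilm region is empty")
    if variant.kind == "constant_mgrow":
        M = np.full(grid.shape, variant.mgrow_value)
    else:
        M = m1.growth_mode(state.cell["G_in"], state.cell["V"], p,
                           variant.literal_tv)
    g_src = p.delta_grow * M * state.cell["G_in"]
    g_src = np.where(inside, g_src, 0.0)

    if literal_form:
        q = np.where(inside, M * state.cell["G_in"], 0.0)
        lap = (np.roll(q, 1, 0) + np.roll(q, -1, 0) + np.roll(q, 1, 1)
               + np.roll(q, -1, 1) - 4 * q) / h**2
        Omega = np.where(inside, p.delta_grow * lap, 0.0)
    else:
        n = int(inside.sum())
        ids = np.full(grid.shape, -1, dtype=int)
        ids[inside] = np.arange(n)
        invh2 = 1.0 / h**2
        A = _Coo()
        diag = np.zeros(n)
        b = g_src[inside].copy()
        for dj, di in _DIRS:
            (cc, nn) = _neighbor_views(ids, dj, di)
            mU = inside[cc] & inside[nn]
            A.add(ids[cc][mU], ids[nn][mU], invh2)
            diag[ids[cc][mU]] -= invh2
            mF = inside[cc] & ~inside[nn]    # interface face: Omega = 0
            diag[ids[cc][mF]] -= 2.0 * invh2
            # domain-edge faces: Neumann 0 (no growth through walls): drop
        A.add(np.arange(n), np.arange(n), 0.0)
        Mmat = A.matrix(n) + sp.diags(diag)
        sol = spla.spsolve(Mmat.tocsc(), b)
        if not np.all(np.isfinite(sol)):
            raise SolverError("growth-potential solve failed")
        Omega = np.zeros(grid.shape)
        Omega[inside] = sol

    # reflected ghost outside the interface keeps the face value at zero;
    # the ghost takes minus the mean of its 4-adjacent inside neighbours
    # (a symmetric construction)
    Om_in = np.where(inside, Omega, 0.0)
    nb_sum = np.zeros(grid.shape)
    nb_cnt = np.zeros(grid.shape)
    for dj, di in _DIRS:
        nb_sum += np.roll(Om_in, (dj, di), axis=(0, 1))
        nb_cnt += np.roll(inside.astype(float), (dj, di), axis=(0, 1))
    ghost_band = ~inside & (nb_cnt > 0)
    refl = -nb_sum / np.maximum(nb_cnt, 1.0)
    Om_ghost = np.where(ghost_band, refl, Om_in)

    Ux = np.gradient(Om_ghost, h, axis=1)
    Uy = np.gradient(Om_ghost, h, axis=0)
    gx = np.gradient(state.phi, h, axis=1)
    gy = np.gradient(state.phi, h, axis=0)
    norm = np.hypot(gx, gy)
    norm[norm < 1e-12] = 1.0
    F_local = (Ux * gx + Uy * gy) / norm
    F = extend_to_everywhere(np.where(inside, F_local, 0.0), inside)
    F = np.maximum(F, 0.0)          # growth only; U points outward
    return Omega, (Ux, Uy), F


# --------------------------------------------------------------------------
# coupled time loop
# --------------------------------------------------------------------------

@dataclass
class Trace2D:
    """Mean-field time series over the biofilm region (area-based), plus
    per-connected-component mean voltage series."""

    time_h: np.ndarray
    area_mm2: np.ndarray
    mean_V_mV: np.ndarray
    mean_K_mM: np.ndarray
    mean_Gin_mM: np.ndarray
    mean_T: np.ndarray
    mean_A: np.ndarray
    per_biofilm_V: np.ndarray       # (n_times, n_components), NaN-padded
    per_biofilm_area: np.ndarray

    def to_dataframe(self):
        import pandas as pd
        d = {"time_h": self.time_h, "area_mm2": self.area_mm2,
             "mean_V_mV": self.mean_V_mV, "mean_K_mM": self.mean_K_mM,
             "mean_Gin_mM": self.mean_Gin_mM, "mean_T": self.mean_T,
             "mean_A": self.mean_A}
        for k in range(self.per_biofilm_V.shape[1]):
            d[f"biofilm{k + 1}_V_mV"] = self.per_biofilm_V[:, k]
            d[f"biofilm{k + 1}_area_mm2"] = self.per_biofilm_area[:, k]
        return pd.DataFrame(d)


def make_state_2d(shape: ShapeSpec, grid: Grid2D, p: ParameterSet,
                  init_values: dict | None = None) -> State2D:
    shape.validate(grid)
    init = dict(DEFAULT_INIT_2D)
    init.update(init_values or {})
    if "T" not in init:
        ex = min(p.g_T * (init["V"] - p.V_0T), 500.0)
        init["T"] = p.alpha_T / ((1.0 + np.exp(ex)) * p.gamma_T)
    if "A" not in init:
        init["A"] = p.alpha_A * init["K"] / p.gamma_A
    phi = signed_distance_from_mask(shape.mask, grid.h)
    cell = {name: np.full(grid.shape, float(init[_CELL_INIT[name]]))
            for name in CELL_FIELDS}
    G = np.full(grid.shape, float(init["G"]))
    K = np.full(grid.shape, float(init["K"]))
    return State2D(grid=grid, phi=phi, G=G, K=K, cell=cell)


_CELL_INIT = {"G_in": "G_in", "K_in": "K_in",
              "K_acclimated": "K_acclimated", "V": "V", "n": "n",
              "T": "T", "A": "A"}


def _reaction_step_2d(state: State2D, p: ParameterSet,
                      variant: m1.VariantSpec, dt: float, n_sub: int):
    """Heun sub-steps of the pointwise reaction terms on the inside cells.

    Returns the (G, K) reaction source fields (mM/hour, inside only) to be
    fed to the implicit transport solve, evaluated consistently with the
    cellular update.
    """
    ins = state.inside
    f = {name: state.cell[name][ins] for name in CELL_FIELDS}
    G = state.G[ins]
    K = state.K[ins]
    leak = 0.0 if variant.kind == "no_leak_uptake" else 1.0
    acclim_off = variant.kind == "no_acclimation"
    dts = dt / n_sub
    srcG_acc = np.zeros_like(G)
    srcK_acc = np.zeros_like(K)

    def rhs(fv, Gv, Kv):
        Kacc = np.zeros_like(Kv) if acclim_off else fv["K_acclimated"]
        V_K, V_L = m1.reversal_potentials(Kv, Kacc, p)
        Jg, Jl, Jp = m1.membrane_exchange(fv["V"], fv["n"], V_K, V_L, Kv,
                                          fv["K_in"], p)
        upt = m1.uptake_glutamate(Gv, fv["G_in"], fv["V"], p)
        if variant.kind == "constant_mgrow":
            M = np.full_like(Gv, variant.mgrow_value)
        else:
            M = m1.growth_mode(fv["G_in"], fv["V"], p, variant.literal_tv)
        d = {}
        d["G_in"] = upt - p.gamma_G * fv["G_in"] * (M + p.r_b)
        d["K_in"] = -Jg - leak * Jl + Jp
        d["K_acclimated"] = (np.zeros_like(Kv) if acclim_off
                             else p.eta_K * (Kv - Kacc))
        d["V"] = (-Jg - Jl - Jp) / p.F
        d["n"] = m1.gate_opening_rate(fv["G_in"], fv["n"], p)
        ex = np.minimum(p.g_T * (fv["V"] - p.V_0T), 500.0)
        d["T"] = p.alpha_T / (1.0 + np.exp(ex)) - p.gamma_T * fv["T"]
        d["A"] = p.alpha_A * Kv - p.gamma_A * fv["A"]
        dG = -upt
        dK = Jg + leak * Jl - Jp
        return d, dG, dK

    for _ in range(n_sub):
        d1, dG1, dK1 = rhs(f, G, K)
        f1 = {k: f[k] + dts * d1[k] for k in f}
        G1 = G + dts * dG1
        K1 = np.maximum(K + dts * dK1, 0.0)
        d2, dG2, dK2 = rhs(f1, G1, K1)
        for k in f:
            f[k] = f[k] + 0.5 * dts * (d1[k] + d2[k])
        srcG_acc += 0.5 * (dG1 + dG2) / n_sub
        srcK_acc += 0.5 * (dK1 + dK2) / n_sub
        G = np.maximum(G + 0.5 * dts * (dG1 + dG2), 0.0)
        K = np.maximum(K + 0.5 * dts * (dK1 + dK2), 0.0)

    f["G_in"] = np.clip(f["G_in"], 0.0, p.G_max)
    f["n"] = np.clip(f["n"], 0.0, 1.0)
    for name in ("K_in", "K_acclimated", "T", "A"):
        f[name] = np.maximum(f[name], 0.0)
    for name in CELL_FIELDS:
        state.cell[name][ins] = f[name]
    srcG = np.zeros(state.grid.shape)
    srcK = np.zeros(state.grid.shape)
    srcG[ins] = srcG_acc
    srcK[ins] = srcK_acc
    return srcG, srcK


def _advect_cell_fields_2d(state: State2D, U: tuple, dt: float):
    """First-order upwind advection of cellular fields with the growth
    velocity, restricted to the biofilm region."""
    Ux, Uy = U
    h = state.grid.h
    ins = state.inside
    for name in CELL_FIELDS:
        q = state.cell[name]
        qx_b = np.zeros_like(q)
        qx_f = np.zeros_like(q)
        qy_b = np.zeros_like(q)
        qy_f = np.zeros_like(q)
        qx_b[:, 1:] = (q[:, 1:] - q[:, :-1]) / h
        qx_f[:, :-1] = (q[:, 1:] - q[:, :-1]) / h
        qy_b[1:, :] = (q[1:, :] - q[:-1, :]) / h
        qy_f[:-1, :] = (q[1:, :] - q[:-1, :]) / h
        adv = (np.maximum(Ux, 0.0) * qx_b + np.minimum(Ux, 0.0) * qx_f
               + np.maximum(Uy, 0.0) * qy_b + np.minimum(Uy, 0.0) * qy_f)
        q[ins] = q[ins] - dt * adv[ins]


def run_2d(shapes: ShapeSpec | list, p: ParameterSet,
           t_end: float,
           grid: Grid2D | None = None,
           init_values: dict | None = None,
           variant: m1.VariantSpec = m1.FULL,
           dt: float = 1.0e-3,
           out_dt: float = 0.02,
           reinit_every: int = 10,
           snapshot_every_h: float | None = None,
           snapshot_fields: tuple = ("V", "K"),
           max_components: int = 4,
           seed: int | None = None):
    """Coupled 2D simulation; returns ``Trace2D`` (and snapshots if asked).

    Snapshots are ``(t, {"phi": φ, field: array, ...})`` captured every
    ``snapshot_every_h`` hours.  The model is deterministic; ``seed`` is
    accepted for interface symmetry.
    """
    if grid is None:
        grid = Grid2D()
    if isinstance(shapes, (list, tuple)):
        mask = np.zeros(grid.shape, dtype=bool)
        for s in shapes:
            mask |= s.mask
        shapes = ShapeSpec(mask=mask)
    state = make_state_2d(shapes, grid, p, init_values)
    if variant.kind == "no_acclimation":
        state.cell["K_acclimated"][:] = 0.0
    pE = variant.apply_to_params(p)
    n_sub = m1._n_substeps(pE, dt)

    records = []
    snaps = []
    state.fluid = solve_pressure_velocity(grid, state.phi, pE)
    opG, opK = _transport_ops(state, pE, dt)
    prev_inside = state.inside.copy()

    t = 0.0
    next_out = 0.0
    next_snap = 0.0 if snapshot_every_h is not None else np.inf
    nsteps = int(round(t_end / dt))
    for istep in range(nsteps + 1):
        if t >= next_out - 1e-9:
            records.append(_record_2d(state, max_components))
            records[-1]["t"] = t
            next_out += out_dt
        if t >= next_snap - 1e-9:
            snap = {"phi": state.phi.copy()}
            for name in snapshot_fields:
                snap[name] = (state.cell[name].copy() if name in CELL_FIELDS
                              else getattr(state, name).copy())
            snaps.append((t, snap))
            next_snap += snapshot_every_h
        if istep == nsteps:
            break

        srcG, srcK = _reaction_step_2d(state, pE, variant, dt, n_sub)
        state.G = opG.step(state.G, srcG)
        state.K = opK.step(state.K, srcK)
        state.G = np.maximum(state.G, 0.0)
        state.K = np.maximum(state.K, 0.0)

        Omega, U, F = growth_potential_velocity(state, pE, variant)
        state.Omega = Omega
        _advect_cell_fields_2d(state, U, dt)
        state.phi = advance_interface(
            state.phi, F, dt, grid.h,
            reinit=(istep % reinit_every == reinit_every - 1))

        inside = state.inside
        newcells = inside & ~prev_inside
        if newcells.any():
            for name in CELL_FIELDS:
                ext = extend_to_everywhere(state.cell[name], prev_inside)
                state.cell[name][newcells] = ext[newcells]
        if (inside != prev_inside).any():
            if inside[:, 0].any() or inside[:, -1].any():
                raise GeometryError("biofilm reached the inlet or outlet")
            state.fluid = solve_pressure_velocity(grid, state.phi, pE)
            opG, opK = _transport_ops(state, pE, dt)
            prev_inside = inside.copy()
        t += dt

    trace = _records_to_trace(records, max_components)
    if snapshot_every_h is not None:
        return trace, snaps
    return trace


def _record_2d(state: State2D, max_components: int) -> dict:
    ins = state.inside
    nin = max(int(ins.sum()), 1)
    rec = {
        "area": state.area_mm2,
        "V": float(state.cell["V"][ins].mean()) if ins.any() else np.nan,
        "K": float(state.K[ins].mean()) if ins.any() else np.nan,
        "Gin": float(state.cell["G_in"][ins].mean()) if ins.any() else np.nan,
        "T": float(state.cell["T"][ins].mean()) if ins.any() else np.nan,
        "A": float(state.cell["A"][ins].mean()) if ins.any() else np.nan,
    }
    lab, ncomp = ndimage.label(ins)
    # stable ordering: components sorted by area desc at each record
    sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                               index=np.arange(1, ncomp + 1))
    order = np.argsort(sizes)[::-1][:max_components]
    pbV = np.full(max_components, np.nan)
    pbA = np.full(max_components, np.nan)
    for k, ci in enumerate(order):
        m = lab == (ci + 1)
        pbV[k] = state.cell["V"][m].mean()
        pbA[k] = m.sum() * state.grid.h**2
    rec["pbV"] = pbV
    rec["pbA"] = pbA
    return rec


def _records_to_trace(records: list, max_components: int) -> Trace2D:
    return Trace2D(
        time_h=np.array([r["t"] for r in records]),
        area_mm2=np.array([r["area"] for r in records]),
        mean_V_mV=np.array([r["V"] for r in records]),
        mean_K_mM=np.array([r["K"] for r in records]),
        mean_Gin_mM=np.array([r["Gin"] for r in records]),
        mean_T=np.array([r["T"] for r in records]),
        mean_A=np.array([r["A"] for r in records]),
        per_biofilm_V=np.vstack([r["pbV"] for r in records]),
        per_biofilm_area=np.vstack([r["pbA"] for r in records]))
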