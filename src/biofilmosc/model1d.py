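"""One-dimensional biofilm cross-section model.

The biofilm occupies [0, L(t)] with a solid wall at x = 0 and the fluid
interface at x = L.  Extracellular glutamate G and potassium K diffuse; the
cellular state variables (internal glutamate G_in, internal potassium K_in,
the acclimated potassium level K_acclimated, membrane voltage V, potassium
gate openness n, and the two fluorescent reporters T/ThT and A/APG) are
carried with the growing biomass and obey an advection term -d(Uq)/dx, where
U(x) is the cumulative growth velocity.

Oscillation mechanism, in brief: starving interior cells (low internal
glutamate) open potassium gates, release K+ and hyperpolarize; the released
potassium raises the leak reversal potential of neighbours above their
acclimated level, depolarizes them, blocks their glutamate uptake, stresses
them in turn, and the potassium wave propagates outward.  Hyperpolarized
cells do not grow (M_grow low), so glutamate penetrates deeper and the
interior recovers, closing the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import _kernel1d as _k
from .params import ParameterSet

__all__ = [
    "Grid1D", "State1D", "VariantSpec", "OscillationTrace",
    "growth_mode", "reversal_potentials", "membrane_exchange",
    "gate_opening_rate", "uptake_glutamate", "boundary_flux",
    "growth_velocity", "rhs_1d", "step_1d", "run_1d",
    "make_grid", "make_initial_state", "DEFAULT_INIT", "IntegrationError",
]

#: Printed initial condition for 1D runs (internal units).
DEFAULT_INIT = {
    "G": 30.0, "K": 8.0, "G_in": 20.0, "K_in": 300.0,
    "K_acclimated": 8.0, "V": -156.0, "n": 0.1,
}

FIELD_NAMES = ("G", "K", "G_in", "K_in", "K_acclimated", "V", "n", "T", "A")

#: Nominal grid spacing, mm (2 µm).
DEFAULT_DX = 0.002
#: Default outer time step bound, hours.
DEFAULT_DT_MAX = 5.0e-4
#: Default trace output interval, hours.
DEFAULT_OUT_DT = 0.02
#: Hard cap on domain length for array pre-allocation, mm.
L_CAP = 2.4


class IntegrationError(RuntimeError):
    """The time stepper failed (NaN/Inf derivative or step-size underflow)."""


@dataclass
class Grid1D:
    """Node positions over [0, L]; uniform spacing except the last interval.

    Interior nodes sit at i*dx; the final node tracks the interface at L
    exactly, with last spacing kept within (0.2, 1.2]*dx by re-gridding.
    """

    x: np.ndarray
    dx: float

    @property
    def L(self) -> float:
        return float(self.x[-1])

    @property
    def n_nodes(self) -> int:
        return len(self.x)

    def widths(self) -> np.ndarray:
        """Finite-volume cell widths (trapezoid quadrature weights)."""
        w = np.empty_like(self.x)
        w[0] = 0.5 * (self.x[1] - self.x[0])
        w[1:-1] = 0.5 * (self.x[2:] - self.x[:-2])
        w[-1] = 0.5 * (self.x[-1] - self.x[-2])
        return w


def make_grid(L: float, dx: float = DEFAULT_DX) -> Grid1D:
    if L <= 0:
        raise ValueError("domain length must be positive")
    n_int = max(3, int(np.floor((L - 0.2 * dx) / dx)) + 1)
    x = np.empty(n_int + 1)
    x[:n_int] = np.arange(n_int) * dx
    x[-1] = L
    return Grid1D(x=x, dx=dx)


@dataclass
class State1D:
    """Spatial fields on a :class:`Grid1D` plus the domain length."""

    grid: Grid1D
    G: np.ndarray
    K: np.ndarray
    G_in: np.ndarray
    K_in: np.ndarray
    K_acclimated: np.ndarray
    V: np.ndarray
    n: np.ndarray
    T: np.ndarray
    A: np.ndarray

    @property
    def L(self) -> float:
        return self.grid.L

    def fields(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, _ATTR[name]) for name in FIELD_NAMES}

    def copy(self) -> "State1D":
        return State1D(
            grid=Grid1D(self.grid.x.copy(), self.grid.dx),
            **{_ATTR[name]: getattr(self, _ATTR[name]).copy()
               for name in FIELD_NAMES})


_ATTR = {"G": "G", "K": "K", "G_in": "G_in", "K_in": "K_in",
         "K_acclimated": "K_acclimated", "V": "V", "n": "n", "T": "T",
         "A": "A"}


@dataclass(frozen=True)
class VariantSpec:
    """Model variant selector for the ablation comparisons.

    ``full``            the complete model;
    ``constant_mgrow``  growth propensity frozen at ``mgrow_value``;
    ``no_acclimation``  cells respond to absolute potassium
                        (K_acclimated ≡ 0, delta_L lowered);
    ``no_leak_uptake``  the leak-gate term is removed from the two potassium
                        balance equations only (it stays in the voltage
                        equation), so potassium cannot leak back into cells.
    """

    kind: Literal["full", "constant_mgrow", "no_acclimation",
                  "no_leak_uptake"] = "full"
    mgrow_value: float = 0.2
    delta_L_override: float = 6.0
    literal_tv: bool = False
    advect_transport: bool = False

    def apply_to_params(self, p: ParameterSet) -> ParameterSet:
        if self.kind == "no_acclimation":
            return p.with_overrides(delta_L=self.delta_L_override)
        return p

    def flags(self) -> np.ndarray:
        fl = np.zeros(_k.NFLAGS, dtype=np.int64)
        fl[_k.FL_ADV_TRANSPORT] = 1 if self.advect_transport else 0
        fl[_k.FL_MGROW_CONST] = 1 if self.kind == "constant_mgrow" else 0
        fl[_k.FL_ACCLIM_OFF] = 1 if self.kind == "no_acclimation" else 0
        fl[_k.FL_LEAK_OFF] = 1 if self.kind == "no_leak_uptake" else 0
        fl[_k.FL_LITERAL_TV] = 1 if self.literal_tv else 0
        return fl


FULL = VariantSpec()


# --------------------------------------------------------------------------
# pointwise model terms (reference implementations, vectorized over nodes)
# --------------------------------------------------------------------------

def growth_mode(G_in, V, p: ParameterSet, literal_tv: bool = False):
    """Growth propensity M_grow in [0, 1].

    M = T_G / (T_G + T_V) with T_G = G_in/(G_in+G_u) a Hill activation in
    internal glutamate and T_V = eta_V*(tanh(gamma_V*(V/V_low - 1)) + 1) a
    tanh activation that is large when the cell is hyperpolarized below
    V_low.  Cells grow only when fed and not hyperpolarized.
    """
    G_in = np.asarray(G_in, dtype=float)
    V = np.asarray(V, dtype=float)
    TG = G_in / (G_in + p.G_u)
    th = np.tanh(p.gamma_V * (V / p.V_low - 1.0))
    TV = (p.eta_V * th + 1.0) if literal_tv else p.eta_V * (th + 1.0)
    den = TG + TV
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(den > 0, TG / np.where(den > 0, den, 1.0),
                     np.where(TG > 0, 1.0, 0.0))
    return np.clip(M, 0.0, 1.0)


def reversal_potentials(K, K_acclimated, p: ParameterSet):
    """(V_K, V_L): gate and leak reversal potentials, mV.

    The leak reversal responds to the *change* in ambient potassium relative
    to the level the cells have acclimated to — the model's key departure
    from absolute-potassium sensing.
    """
    K = np.asarray(K, dtype=float)
    K_acclimated = np.asarray(K_acclimated, dtype=float)
    V_K = p.V_K0 + p.delta_K * K
    V_L = p.V_L0 + p.delta_L * (K - K_acclimated)
    return V_K, V_L


def membrane_exchange(V, n, V_K, V_L, K, K_in, p: ParameterSet):
    """(J_gate, J_leak, J_pump) in mM/hour, positive = K+ released.

    Hodgkin–Huxley-style gate flux F*g_K*n^4*(V-V_K), leak flux
    F*g_L*(V-V_L), and the active pump max(gamma_K*K*(K_max-K_in), 0) through
    which cells can only take potassium up, never release it.
    """
    V, n = np.asarray(V, dtype=float), np.asarray(n, dtype=float)
    J_gate = p.F * p.g_K * n**4 * (V - np.asarray(V_K, dtype=float))
    J_leak = p.F * p.g_L * (V - np.asarray(V_L, dtype=float))
    J_pump = np.maximum(
        p.gamma_K * np.asarray(K, dtype=float)
        * (p.K_max - np.asarray(K_in, dtype=float)), 0.0)
    return J_gate, J_leak, J_pump


def gate_opening_rate(G_in, n, p: ParameterSet):
    """dn/dt reaction part: starvation-activated opening minus decay.

    The opening term is a reversed Hill function of internal glutamate,
    large when G_in < G_l (starving cells open their gates and release
    potassium); (G_max - G_in) is clamped at 0 for G_in above G_max.
    """
    G_in = np.asarray(G_in, dtype=float)
    n = np.asarray(n, dtype=float)
    c = np.maximum(p.G_max - G_in, 0.0)
    h = c**p.m / ((p.G_max - p.G_l) ** p.m + c**p.m)
    return p.alpha * h * (1.0 - n) - p.beta * n


def uptake_glutamate(G, G_in, V, p: ParameterSet):
    """Voltage-gated glutamate uptake, mM/hour.

    Uptake shuts off exponentially as V rises above V_th (depolarized cells
    cannot import glutamate) and saturates as G_in approaches G_max.
    """
    G = np.asarray(G, dtype=float)
    G_in = np.asarray(G_in, dtype=float)
    V = np.asarray(V, dtype=float)
    sig = 1.0 / (1.0 + np.exp(V - p.V_th))
    return p.delta_G * sig * G * np.maximum(p.G_max - G_in, 0.0)


def boundary_flux(c_int, c_far, D_biofilm, D_fluid, B_L):
    """Interface gradient dc/dx at x = L from the boundary-layer closure.

    Continuity of flux across the boundary layer gives
    D_biofilm * dc/dx = D_fluid * (c_far - c_int) / B_L.
    """
    return D_fluid * (c_far - c_int) / (B_L * D_biofilm)


def growth_velocity(state: State1D, p: ParameterSet,
                    variant: VariantSpec = FULL):
    """(U field in mm/hour, dL/dt).  U(0) = 0 and U is non-decreasing."""
    if variant.kind == "constant_mgrow":
        M = np.full_like(state.G_in, variant.mgrow_value)
    else:
        M = growth_mode(state.G_in, state.V, p, variant.literal_tv)
    g = p.delta_grow * state.G_in * M
    x = state.grid.x
    U = np.concatenate(
        ([0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(x))))
    return U, float(U[-1])


# --------------------------------------------------------------------------
# full right-hand side (pure-numpy reference; the compiled kernel is the
# production path and a test pins the two against each other)
# --------------------------------------------------------------------------

def rhs_1d(state: State1D, p: ParameterSet, variant: VariantSpec = FULL,
           closed: bool = False, growth_off: bool = False) -> dict:
    """Time derivatives of every field, including spatial terms.

    Diffusion uses the same finite-volume stencil as the stepper (wall
    no-flux, interface Robin closure via :func:`boundary_flux`); advection is
    first-order conservative upwind.  Returns a dict of arrays plus
    ``dL_dt``.  Raises :class:`IntegrationError` on non-finite derivatives.
    """
    x = state.grid.x
    N = len(x)
    w = state.grid.widths()
    pE = variant.apply_to_params(p)

    K_acc = np.zeros_like(state.K) if variant.kind == "no_acclimation" \
        else state.K_acclimated
    V_K, V_L = reversal_potentials(state.K, K_acc, pE)
    J_gate, J_leak, J_pump = membrane_exchange(
        state.V, state.n, V_K, V_L, state.K, state.K_in, pE)
    upt = uptake_glutamate(state.G, state.G_in, state.V, pE)
    if variant.kind == "constant_mgrow":
        M = np.full_like(state.G_in, variant.mgrow_value)
    else:
        M = growth_mode(state.G_in, state.V, pE, variant.literal_tv)
    leak = 0.0 if variant.kind == "no_leak_uptake" else 1.0

    d = {}
    d["G"] = -upt + _diffusion_term(state.G, x, w, pE.D_G, pE.D_G_fl,
                                    pE.B_L, pE.G0, closed)
    d["K"] = (J_gate + leak * J_leak - J_pump
              + _diffusion_term(state.K, x, w, pE.D_K, pE.D_K_fl,
                                pE.B_L, pE.K0, closed))
    d["G_in"] = upt - pE.gamma_G * state.G_in * (M + pE.r_b)
    d["K_in"] = -J_gate - leak * J_leak + J_pump
    d["K_acclimated"] = (np.zeros_like(state.K)
                         if variant.kind == "no_acclimation"
                         else pE.eta_K * (state.K - K_acc))
    d["V"] = (-J_gate - J_leak - J_pump) / pE.F
    d["n"] = gate_opening_rate(state.G_in, state.n, pE)
    ex = np.minimum(pE.g_T * (state.V - pE.V_0T), 500.0)
    d["T"] = pE.alpha_T / (1.0 + np.exp(ex)) - pE.gamma_T * state.T
    d["A"] = pE.alpha_A * state.K - pE.gamma_A * state.A

    if growth_off:
        U = np.zeros(N)
        dLdt = 0.0
    else:
        U, dLdt = growth_velocity(state, pE, variant)
        for name in ("G_in", "K_in", "K_acclimated", "V", "n", "T", "A"):
            d[name] = d[name] + _advection_term(
                getattr(state, _ATTR[name]), U, x, w)
    d["dL_dt"] = dLdt

    for name, arr in d.items():
        if not np.all(np.isfinite(arr)):
            raise IntegrationError(f"non-finite derivative in field {name}")
    return d


def _diffusion_term(q, x, w, D, Dfl, BL, cfar, closed):
    N = len(x)
    out = np.zeros(N)
    flux = D * np.diff(q) / np.diff(x)          # flux at interior faces
    out[0] = flux[0] / w[0]
    out[1:-1] = (flux[1:] - flux[:-1]) / w[1:-1]
    bflux = 0.0 if closed else Dfl * (cfar - q[-1]) / BL
    out[-1] = (bflux - flux[-1]) / w[-1]
    return out


def _advection_term(q, U, x, w):
    N = len(x)
    out = np.zeros(N)
    Uf = 0.5 * (U[:-1] + U[1:])
    fl = Uf * q[:-1]                             # upwind (U >= 0)
    out[0] = -fl[0] / w[0]
    out[1:-1] = -(fl[1:] - fl[:-1]) / w[1:-1]
    out[-1] = -q[-1] * (U[-1] - U[-2]) / (x[-1] - x[-2])
    return out


# --------------------------------------------------------------------------
# time stepping
# --------------------------------------------------------------------------

def make_initial_state(width_mm: float, p: ParameterSet,
                       init_values: dict | None = None,
                       dx: float = DEFAULT_DX) -> State1D:
    """Uniform initial state at the printed initial condition.

    The fluorescent reporters are not part of the printed initial condition;
    they start at their per-cell steady state for the initial V and K (they
    do not feed back on the dynamics).
    """
    init = dict(DEFAULT_INIT)
    init.update(init_values or {})
    grid = make_grid(width_mm, dx)
    N = grid.n_nodes
    if "T" not in init:
        ex = min(p.g_T * (init["V"] - p.V_0T), 500.0)
        init["T"] = p.alpha_T / ((1.0 + np.exp(ex)) * p.gamma_T)
    if "A" not in init:
        init["A"] = p.alpha_A * init["K"] / p.gamma_A
    return State1D(grid=grid, **{
        _ATTR[name]: np.full(N, float(init[name])) for name in FIELD_NAMES})


def _n_substeps(p: ParameterSet, dt: float) -> int:
    # conservative reaction-Jacobian bound; depends only on the parameters so
    # that runs with perturbed parameters follow identical step schedules
    n_hi = min(1.0, 1.1 * p.alpha / (p.alpha + p.beta))
    lam = (p.F * p.g_K * n_hi**4 * (1.0 + p.delta_K)
           + p.F * p.g_L * (1.0 + p.delta_L)
           + 1.2 * p.delta_G * p.G0
           + p.gamma_K * p.K_max + p.eta_K + p.gamma_T + p.gamma_A
           + p.alpha + p.beta + p.gamma_G)
    return max(1, int(np.ceil(dt * lam / 0.9)))


def _kernel_buffers(width_mm: float, dx: float, t_end: float, out_dt: float):
    nmax = int(np.ceil(L_CAP / dx)) + 4
    n_out = int(np.floor(t_end / out_dt + 1e-9)) + 2
    F = np.zeros((_k.NFIELDS, nmax))
    x = np.zeros(nmax)
    TR = np.zeros((_k.NTRACE, n_out))
    return F, x, TR


def _load_state(F, x, state: State1D):
    N = state.grid.n_nodes
    x[:N] = state.grid.x
    for row, name in zip(range(_k.NFIELDS), FIELD_NAMES):
        F[row, :N] = getattr(state, _ATTR[name])
    return N


def _unload_state(F, x, N, dx) -> State1D:
    grid = Grid1D(x=x[:N].copy(), dx=dx)
    kw = {_ATTR[name]: F[row, :N].copy()
          for row, name in zip(range(_k.NFIELDS), FIELD_NAMES)}
    return State1D(grid=grid, **kw)


def step_1d(state: State1D, p: ParameterSet, dt_max: float = DEFAULT_DT_MAX,
            variant: VariantSpec = FULL, closed: bool = False,
            growth_off: bool = False, t_span: float | None = None) -> State1D:
    """Advance the state by ``t_span`` (default: one outer step ``dt_max``)."""
    if p.units != "internal":
        raise ValueError("parameters must be in internal units")
    t_end = dt_max if t_span is None else t_span
    F, x, TR = _kernel_buffers(state.L, state.grid.dx, t_end, t_end)
    N = _load_state(F, x, state)
    fl = variant.flags()
    fl[_k.FL_CLOSED] = 1 if closed else 0
    fl[_k.FL_GROWTH_OFF] = 1 if growth_off else 0
    pE = variant.apply_to_params(p)
    status, N, L, t, _, _ = _k.integrate_1d(
        F, x, N, state.L, _k.pack_params(pE), fl, variant.mgrow_value,
        0.0, t_end, dt_max, _n_substeps(pE, dt_max), t_end, t_end, TR, 0, 0)
    _raise_on_status(status)
    return _unload_state(F, x, N, state.grid.dx)


def _raise_on_status(status: int):
    if status == _k.STATUS_NONFINITE:
        raise IntegrationError("non-finite field value during integration")
    if status == _k.STATUS_STIFF:
        raise IntegrationError(
            "step-size underflow or domain overflow in the 1D stepper")


@dataclass
class OscillationTrace:
    """Time series of spatial means over the biofilm and of its size."""

    time_h: np.ndarray
    width_mm: np.ndarray
    dLdt_mm_per_h: np.ndarray
    mean_V_mV: np.ndarray
    mean_K_mM: np.ndarray
    mean_Gin_mM: np.ndarray
    mean_Kin_mM: np.ndarray
    mean_T: np.ndarray
    mean_A: np.ndarray
    area_mm2: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_h": self.time_h, "width_mm": self.width_mm,
                "dLdt_mm_per_h": self.dLdt_mm_per_h,
                "mean_V_mV": self.mean_V_mV, "mean_K_mM": self.mean_K_mM,
                "mean_Gin_mM": self.mean_Gin_mM,
                "mean_Kin_mM": self.mean_Kin_mM,
                "mean_T": self.mean_T, "mean_A": self.mean_A}
        if self.area_mm2 is not None:
            cols["area_mm2"] = self.area_mm2
        return pd.DataFrame(cols)

    def __len__(self) -> int:
        return len(self.time_h)


def run_1d(initial_width: float, p: ParameterSet,
           t_end: float,
           init_values: dict | None = None,
           variant: VariantSpec = FULL,
           dx: float = DEFAULT_DX,
           dt_max: float = DEFAULT_DT_MAX,
           out_dt: float = DEFAULT_OUT_DT,
           snapshot_every_h: float | None = None,
           seed: int | None = None) -> OscillationTrace | tuple:
    """Simulate the 1D model and return the mean-field trace.

    Parameters
    ----------
    initial_width
        Initial biofilm width L(0) in mm.
    t_end
        Simulation horizon in hours.  ``t_end == 0`` returns a single-record
        trace of the initial state.
    snapshot_every_h
        If set, full-field snapshots are captured at this interval and the
        return value is ``(trace, snapshots)`` with snapshots a list of
        ``(t, State1D)``.

    The model itself is deterministic; ``seed`` is accepted for interface
    symmetry with the replicate experiments and is unused here.
    """
    if p.units != "internal":
        raise ValueError("parameters must be in internal units")
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    state = make_initial_state(initial_width, p, init_values, dx)
    pE = variant.apply_to_params(p)
    if variant.kind == "no_acclimation":
        state.K_acclimated[:] = 0.0

    F, x, TR = _kernel_buffers(initial_width, dx, max(t_end, out_dt), out_dt)
    N = _load_state(F, x, state)
    fl = variant.flags()
    pv = _k.pack_params(pE)
    n_sub = _n_substeps(pE, dt_max)

    snapshots = []
    if snapshot_every_h is None:
        seg_ends = [t_end]
    else:
        seg_ends = list(np.arange(snapshot_every_h, t_end,
                                  snapshot_every_h)) + [t_end]
        snapshots.append((0.0, _unload_state(F, x, N, dx)))

    t, L, out_idx, out_next = 0.0, initial_width, 0, 0.0
    record_initial = 1
    for seg_end in seg_ends:
        if seg_end > t:
            status, N, L, t, out_idx, out_next = _k.integrate_1d(
                F, x, N, L, pv, fl, variant.mgrow_value, t, seg_end, dt_max,
                n_sub, out_next, out_dt, TR, out_idx, record_initial)
            record_initial = 0
            _raise_on_status(status)
        if snapshot_every_h is not None:
            snapshots.append((t, _unload_state(F, x, N, dx)))
    if t_end == 0.0:
        # single initial record
        w = state.grid.widths()
        TR[:, 0] = [0.0, state.L, growth_velocity(state, pE, variant)[1],
                    np.sum(w * state.V) / state.L,
                    np.sum(w * state.K) / state.L,
                    np.sum(w * state.G_in) / state.L,
                    np.sum(w * state.K_in) / state.L,
                    np.sum(w * state.T) / state.L,
                    np.sum(w * state.A) / state.L]
        out_idx = 1

    trace = OscillationTrace(
        time_h=TR[0, :out_idx].copy(), width_mm=TR[1, :out_idx].copy(),
        dLdt_mm_per_h=TR[2, :out_idx].copy(),
        mean_V_mV=TR[3, :out_idx].copy(), mean_K_mM=TR[4, :out_idx].copy(),
        mean_Gin_mM=TR[5, :out_idx].copy(),
        mean_Kin_mM=TR[6, :out_idx].copy(),
        mean_T=TR[7, :out_idx].copy(), mean_A=TR[8, :out_idx].copy())
    if snapshot_every_h is not None:
        return trace, snapshots
    return trace
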