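"""Compiled inner loop of the 1D moving-domain solver.

The 1D model is a reaction–advection–diffusion system on [0, L(t)] with a
moving fluid interface at x = L.  The grid keeps interior nodes at fixed
positions i·dx and one interface node exactly at L; nodes are appended as the
biofilm grows, new nodes inheriting the previous interface value (constant
extrapolation).  One outer step applies, in order:

1. explicit Heun (RK2) sub-steps for the pointwise reaction terms,
2. explicit first-order conservative upwind advection of the cellular
   (non-diffusive) fields with the growth velocity U ≥ 0,
3. backward-Euler diffusion for extracellular G and K with the boundary-layer
   Robin closure at x = L and a no-flux wall at x = 0 (Thomas solve),
4. interface motion dL/dt = U(L) and re-gridding.

Everything here is numba-compiled; the pure-numpy reference right-hand side
lives in :mod:`biofilmosc.model1d` and a test pins the two against each other.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- parameter vector layout (keep in sync with pack_params) ---------------
(P_DG, P_DK, P_DGFL, P_DKFL, P_G0, P_K0, P_DELTAG, P_VTH, P_GMAX, P_F,
 P_GK, P_GL, P_GAMMAK, P_BL, P_GAMMAG, P_RB, P_GU, P_ETAV, P_GAMMAV,
 P_VLOW, P_DELTAGROW, P_ETAK, P_ALPHA, P_BETA, P_M, P_GLOW, P_VK0, P_VL0,
 P_DELTAK, P_DELTAL, P_ALPHAT, P_GT, P_V0T, P_GAMMAT, P_ALPHAA, P_GAMMAA,
 P_KMAX) = range(37)

_PACK_ORDER = (
    "D_G", "D_K", "D_G_fl", "D_K_fl", "G0", "K0", "delta_G", "V_th",
    "G_max", "F", "g_K", "g_L", "gamma_K", "B_L", "gamma_G", "r_b",
    "G_u", "eta_V", "gamma_V", "V_low", "delta_grow", "eta_K", "alpha",
    "beta", "m", "G_l", "V_K0", "V_L0", "delta_K", "delta_L", "alpha_T",
    "g_T", "V_0T", "gamma_T", "alpha_A", "gamma_A", "K_max",
)

# flag vector layout
(FL_MGROW_CONST, FL_ACCLIM_OFF, FL_LEAK_OFF, FL_GROWTH_OFF,
 FL_CLOSED, FL_LITERAL_TV, FL_ADV_TRANSPORT) = range(7)
NFLAGS = 7

# field row layout in the state matrix
(IG, IK, IGIN, IKIN, IKACC, IV, IN, IT, IA) = range(9)
NFIELDS = 9

# trace row layout
NTRACE = 9  # time, L, dLdt, meanV, meanK, meanGin, meanKin, meanT, meanA

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_STIFF = 2


def pack_params(p) -> np.ndarray:
    """Flatten an internal-unit ParameterSet into the kernel's vector."""
    assert p.units == "internal", "kernel expects internal units"
    return np.array([getattr(p, name) for name in _PACK_ORDER], dtype=np.float64)


@njit(cache=True, fastmath=False)
def _mgrow(Gin, V, pv, fl, mgrow_value):
    if fl[FL_MGROW_CONST] == 1:
        return mgrow_value
    TG = Gin / (Gin + pv[P_GU])
    th = np.tanh(pv[P_GAMMAV] * (V / pv[P_VLOW] - 1.0))
    if fl[FL_LITERAL_TV] == 1:
        TV = pv[P_ETAV] * th + 1.0
    else:
        TV = pv[P_ETAV] * (th + 1.0)
    den = TG + TV
    if den <= 0.0:
        return 1.0 if TG > 0.0 else 0.0
    M = TG / den
    if M < 0.0:
        M = 0.0
    elif M > 1.0:
        M = 1.0
    return M


@njit(cache=True, fastmath=False)
def _reaction_rhs(F, dF, N, pv, fl, mgrow_value):
    """Pointwise (non-spatial) derivatives of all nine fields."""
    for i in range(N):
        G = F[IG, i]
        K = F[IK, i]
        Gin = F[IGIN, i]
        Kin = F[IKIN, i]
        Kacc = F[IKACC, i]
        V = F[IV, i]
        n = F[IN, i]
        T = F[IT, i]
        A = F[IA, i]

        sig = 1.0 / (1.0 + np.exp(V - pv[P_VTH]))
        need = pv[P_GMAX] - Gin
        if need < 0.0:
            need = 0.0
        uptake = pv[P_DELTAG] * sig * G * need

        M = _mgrow(Gin, V, pv, fl, mgrow_value)

        VK = pv[P_VK0] + pv[P_DELTAK] * K
        if fl[FL_ACCLIM_OFF] == 1:
            VL = pv[P_VL0] + pv[P_DELTAL] * K
        else:
            VL = pv[P_VL0] + pv[P_DELTAL] * (K - Kacc)

        n4 = n * n * n * n
        Jg = pv[P_F] * pv[P_GK] * n4 * (V - VK)
        Jl = pv[P_F] * pv[P_GL] * (V - VL)
        Jp = pv[P_GAMMAK] * K * (pv[P_KMAX] - Kin)
        if Jp < 0.0:
            Jp = 0.0

        leak = 0.0 if fl[FL_LEAK_OFF] == 1 else 1.0

        dF[IG, i] = -uptake
        dF[IK, i] = Jg + leak * Jl - Jp
        dF[IGIN, i] = uptake - pv[P_GAMMAG] * Gin * (M + pv[P_RB])
        dF[IKIN, i] = -Jg - leak * Jl + Jp
        if fl[FL_ACCLIM_OFF] == 1:
            dF[IKACC, i] = 0.0
        else:
            dF[IKACC, i] = pv[P_ETAK] * (K - Kacc)
        dF[IV, i] = (-Jg - Jl - Jp) / pv[P_F]

        c = pv[P_GMAX] - Gin
        if c < 0.0:
            c = 0.0
        cm = c ** pv[P_M]
        h = cm / ((pv[P_GMAX] - pv[P_GLOW]) ** pv[P_M] + cm)
        dF[IN, i] = pv[P_ALPHA] * h * (1.0 - n) - pv[P_BETA] * n

        ex = pv[P_GT] * (V - pv[P_V0T])
        if ex > 500.0:
            ex = 500.0
        dF[IT, i] = pv[P_ALPHAT] / (1.0 + np.exp(ex)) - pv[P_GAMMAT] * T
        dF[IA, i] = pv[P_ALPHAA] * K - pv[P_GAMMAA] * A


@njit(cache=True, fastmath=False)
def _growth_velocity(F, x, N, pv, fl, mgrow_value, U):
    """U(x) = delta_grow * cumulative trapezoid of G_in*M_grow; U(0)=0."""
    if fl[FL_GROWTH_OFF] == 1:
        for i in range(N):
            U[i] = 0.0
        return
    gprev = pv[P_DELTAGROW] * F[IGIN, 0] * _mgrow(F[IGIN, 0], F[IV, 0],
                                                  pv, fl, mgrow_value)
    U[0] = 0.0
    for i in range(1, N):
        g = pv[P_DELTAGROW] * F[IGIN, i] * _mgrow(F[IGIN, i], F[IV, i],
                                                  pv, fl, mgrow_value)
        U[i] = U[i - 1] + 0.5 * (g + gprev) * (x[i] - x[i - 1])
        gprev = g


@njit(cache=True, fastmath=False)
def _cell_widths(x, N, w):
    w[0] = 0.5 * (x[1] - x[0])
    for i in range(1, N - 1):
        w[i] = 0.5 * (x[i + 1] - x[i - 1])
    w[N - 1] = 0.5 * (x[N - 1] - x[N - 2])


@njit(cache=True, fastmath=False)
def _advect(F, row, U, x, w, N, dt, buf):
    """Conservative first-order upwind step for one cellular field.

    U >= 0 always, so the upwind value at each face is the left node.  The
    interface node moves with the flow (speed U(L)); in its co-moving frame
    only the dilution term -q * dU/dx remains.
    """
    for i in range(N):
        buf[i] = F[row, i]
    fl_prev = 0.0  # wall face flux (U(0)=0)
    for i in range(N - 1):
        uf = 0.5 * (U[i] + U[i + 1])
        fl_i = uf * buf[i]
        F[row, i] = buf[i] - dt * (fl_i - fl_prev) / w[i]
        fl_prev = fl_i
    hl = x[N - 1] - x[N - 2]
    dudx = (U[N - 1] - U[N - 2]) / hl
    F[row, N - 1] = buf[N - 1] * (1.0 - dt * dudx)


@njit(cache=True, fastmath=False)
def _advect_transport(F, row, U, x, N, dt, buf):
    """Non-conservative (material transport) upwind step: dq/dt = -U dq/dx.

    A material quantity carried by the growth flow keeps its per-cell value;
    there is no dilution term.  The interface node is itself a material
    point (it moves at U(L)), so its value is unchanged by transport.
    """
    for i in range(N):
        buf[i] = F[row, i]
    for i in range(1, N - 1):
        g = (buf[i] - buf[i - 1]) / (x[i] - x[i - 1])
        F[row, i] = buf[i] - dt * U[i] * g


@njit(cache=True, fastmath=False)
def _diffuse_be(F, row, x, w, N, dt, D, Dfl, BL, cfar, closed,
                a, b, c, r):
    """Backward-Euler diffusion with wall no-flux and interface Robin BC."""
    # assemble tridiagonal
    hp = x[1] - x[0]
    b[0] = 1.0 + dt * D / (hp * w[0])
    c[0] = -dt * D / (hp * w[0])
    r[0] = F[row, 0]
    for i in range(1, N - 1):
        hm = x[i] - x[i - 1]
        hp = x[i + 1] - x[i]
        a[i] = -dt * D / (hm * w[i])
        c[i] = -dt * D / (hp * w[i])
        b[i] = 1.0 - a[i] - c[i]
        r[i] = F[row, i]
    hm = x[N - 1] - x[N - 2]
    a[N - 1] = -dt * D / (hm * w[N - 1])
    b[N - 1] = 1.0 - a[N - 1]
    r[N - 1] = F[row, N - 1]
    if closed == 0:
        rob = dt * Dfl / (BL * w[N - 1])
        b[N - 1] += rob
        r[N - 1] += rob * cfar
    # Thomas solve
    for i in range(1, N):
        mfac = a[i] / b[i - 1]
        b[i] = b[i] - mfac * c[i - 1]
        r[i] = r[i] - mfac * r[i - 1]
    F[row, N - 1] = r[N - 1] / b[N - 1]
    for i in range(N - 2, -1, -1):
        F[row, i] = (r[i] - c[i] * F[row, i + 1]) / b[i]


@njit(cache=True, fastmath=False)
def _clamp(F, N, gmax):
    for i in range(N):
        if F[IG, i] < 0.0:
            F[IG, i] = 0.0
        if F[IK, i] < 0.0:
            F[IK, i] = 0.0
        if F[IGIN, i] < 0.0:
            F[IGIN, i] = 0.0
        elif F[IGIN, i] > gmax:
            F[IGIN, i] = gmax
        if F[IKIN, i] < 0.0:
            F[IKIN, i] = 0.0
        if F[IKACC, i] < 0.0:
            F[IKACC, i] = 0.0
        if F[IN, i] < 0.0:
            F[IN, i] = 0.0
        elif F[IN, i] > 1.0:
            F[IN, i] = 1.0
        if F[IT, i] < 0.0:
            F[IT, i] = 0.0
        if F[IA, i] < 0.0:
            F[IA, i] = 0.0


@njit(cache=True, fastmath=False)
def _record(TR, k, t, L, dLdt, F, w, N):
    TR[0, k] = t
    TR[1, k] = L
    TR[2, k] = dLdt
    for jr, row in zip((3, 4, 5, 6, 7, 8), (IV, IK, IGIN, IKIN, IT, IA)):
        s = 0.0
        for i in range(N):
            s += w[i] * F[row, i]
        TR[jr, k] = s / L


@njit(cache=True, fastmath=False)
def integrate_1d(F, x, N, L, pv, fl, mgrow_value, t, t_end, dt_max, n_sub,
                 out_next, out_dt, TR, out_idx, record_initial):
    """Advance the 1D state from t to t_end, recording the mean trace.

    Returns (status, N, L, t, out_idx, out_next).
    """
    NMAX = x.shape[0]
    U = np.empty(NMAX)
    w = np.empty(NMAX)
    k1 = np.empty((NFIELDS, NMAX))
    k2 = np.empty((NFIELDS, NMAX))
    ytmp = np.empty((NFIELDS, NMAX))
    ta = np.empty(NMAX)
    tb = np.empty(NMAX)
    tc = np.empty(NMAX)
    tr = np.empty(NMAX)
    buf = np.empty(NMAX)

    _cell_widths(x, N, w)
    _growth_velocity(F, x, N, pv, fl, mgrow_value, U)
    dLdt = U[N - 1]
    if record_initial == 1:
        _record(TR, out_idx, t, L, dLdt, F, w, N)
        out_idx += 1
        out_next = t + out_dt

    eps = 1e-12
    while t < t_end - eps:
        dt = dt_max
        if t + dt > t_end:
            dt = t_end - t

        # --- reactions: n_sub Heun sub-steps with a stiffness retry -------
        nsub = n_sub
        level = 0
        while True:
            ok = True
            for rrow in range(NFIELDS):
                for i in range(N):
                    ytmp[rrow, i] = F[rrow, i]
            dts = dt / nsub
            for _s in range(nsub):
                _reaction_rhs(ytmp, k1, N, pv, fl, mgrow_value)
                for rrow in range(NFIELDS):
                    for i in range(N):
                        k2[rrow, i] = ytmp[rrow, i] + dts * k1[rrow, i]
                _reaction_rhs(k2, k2, N, pv, fl, mgrow_value)
                maxdv = 0.0
                for rrow in range(NFIELDS):
                    for i in range(N):
                        ytmp[rrow, i] = ytmp[rrow, i] + 0.5 * dts * (
                            k1[rrow, i] + k2[rrow, i])
                        if not np.isfinite(ytmp[rrow, i]):
                            ok = False
                for i in range(N):
                    dv = dts * 0.5 * (k1[IV, i] + k2[IV, i])
                    if dv < 0.0:
                        dv = -dv
                    if dv > maxdv:
                        maxdv = dv
                if (not ok) or maxdv > 100.0:
                    ok = False
                    break
            if ok:
                for rrow in range(NFIELDS):
                    for i in range(N):
                        F[rrow, i] = ytmp[rrow, i]
                break
            level += 1
            if level > 18:
                return (STATUS_STIFF, N, L, t, out_idx, out_next)
            nsub *= 2

        # --- growth velocity on the post-reaction state -------------------
        _growth_velocity(F, x, N, pv, fl, mgrow_value, U)
        dLdt = U[N - 1]

        # --- advection of cellular fields ---------------------------------
        if fl[FL_GROWTH_OFF] == 0:
            for rrow in (IGIN, IKIN, IKACC, IV, IN, IT, IA):
                if fl[FL_ADV_TRANSPORT] == 1:
                    _advect_transport(F, rrow, U, x, N, dt, buf)
                else:
                    _advect(F, rrow, U, x, w, N, dt, buf)

        # --- implicit diffusion of extracellular G, K ---------------------
        _diffuse_be(F, IG, x, w, N, dt, pv[P_DG], pv[P_DGFL], pv[P_BL],
                    pv[P_G0], fl[FL_CLOSED], ta, tb, tc, tr)
        _diffuse_be(F, IK, x, w, N, dt, pv[P_DK], pv[P_DKFL], pv[P_BL],
                    pv[P_K0], fl[FL_CLOSED], ta, tb, tc, tr)

        # --- interface motion and re-gridding ------------------------------
        if fl[FL_GROWTH_OFF] == 0:
            L = L + dt * dLdt
            x[N - 1] = L
            dx = x[1] - x[0]
            while L - x[N - 2] > 1.2 * dx and N < NMAX:
                # promote: new interior node where the interface used to
                # live is filled by the interface value (constant
                # extrapolation), interface node keeps its value
                xn_new = x[N - 2] + dx
                x[N] = L
                x[N - 1] = xn_new
                for rrow in range(NFIELDS):
                    F[rrow, N] = F[rrow, N - 1]
                N += 1
            if N >= NMAX - 1:
                return (STATUS_STIFF, N, L, t, out_idx, out_next)
            _cell_widths(x, N, w)

        _clamp(F, N, pv[P_GMAX])
        t = t + dt

        for rrow in range(NFIELDS):
            for i in range(N):
                if not np.isfinite(F[rrow, i]):
                    return (STATUS_NONFINITE, N, L, t, out_idx, out_next)

        if t >= out_next - 1e-9 and out_idx < TR.shape[1]:
            _record(TR, out_idx, t, L, dLdt, F, w, N)
            out_idx += 1
            out_next += out_dt

    return (STATUS_OK, N, L, t, out_idx, out_next)
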