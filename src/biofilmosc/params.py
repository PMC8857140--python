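"""Model constants, unit normalization, and validation.

All tabulated constants of the biofilm potassium-signaling model live in a
single :class:`ParameterSet`.  The published table mixes per-day diffusivities
with per-hour rates; internally everything is normalized to one consistent
system — millimetres, hours, millimolar, millivolts — so that the solvers
never carry unit conversions.

Two unit tags are understood:

``paper``
    The units of the published table (diffusivities in mm²/day, everything
    else already in the internal system).
``internal``
    {mm, hour, mM, mV}.  Diffusivities in mm²/hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "ParameterSet",
    "ConfigurationError",
    "ValidationError",
    "load_parameters",
    "normalize_units",
    "denormalize_units",
    "PAPER_UNITS",
    "INTERNAL_UNITS",
    "SENSITIVITY_PARAMETERS",
]

PAPER_UNITS = "paper"
INTERNAL_UNITS = "internal"

#: Fields converted mm²/day → mm²/hour on normalization.
_DIFFUSIVITY_FIELDS = ("D_G", "D_K", "D_G_fl", "D_K_fl")

#: Reporter-only parameters: excluded from the sensitivity table because they
#: convert voltage/potassium to fluorescence but do not feed back on dynamics.
REPORTER_PARAMETERS = ("alpha_T", "g_T", "V_0T", "gamma_T", "alpha_A", "gamma_A")

#: The 30 parameters of the published sensitivity table, in its row order.
SENSITIVITY_PARAMETERS = (
    "D_G", "D_K", "D_G_fl", "D_K_fl", "G0", "K0", "delta_G", "V_th",
    "G_max", "F", "g_K", "g_L", "gamma_K", "B_L", "gamma_G", "r_b",
    "G_u", "eta_V", "gamma_V", "V_low", "delta_grow", "eta_K", "alpha",
    "beta", "m", "G_l", "V_K0", "V_L0", "delta_K", "delta_L",
)


class ConfigurationError(ValueError):
    """An override names an unknown parameter or carries a non-finite value."""


class ValidationError(ValueError):
    """One or more physical-sanity invariants are violated."""


@dataclass(frozen=True)
class ParameterSet:
    """All model constants, tagged with the unit system they are stored in.

    Defaults are the published values (paper units).  ``K_max`` is used by
    the potassium-pump term but is not tabulated in the source; the default
    300 mM equals the printed homeostatic initial internal potassium, so the
    pump sits exactly at its off threshold at the initial condition.  ``mu``
    (fluid viscosity) only rescales the pressure field under the
    velocity-Dirichlet boundary conditions used here, so 1 in internal units
    is adequate.  ``u0`` is the inlet centerline speed of the 2D flow cell.
    """

    # Diffusion, mm²/day in paper units
    D_G: float = 0.540
    D_K: float = 0.497
    D_G_fl: float = 0.900
    D_K_fl: float = 4.97
    # Inlet concentrations, mM
    G0: float = 30.0
    K0: float = 8.0
    # Glutamate uptake
    delta_G: float = 10.0       # 1/hour
    V_th: float = -150.0        # mV, uptake cutoff
    G_max: float = 20.0         # mM, max internal glutamate
    # Membrane potassium exchange
    F: float = 5.6              # mM/mV
    g_K: float = 180.0          # 1/hour
    g_L: float = 1.2            # 1/hour
    gamma_K: float = 0.025      # 1/(hour·mM)
    # Interface boundary layer (1D closure)
    B_L: float = 0.5            # mm
    # Consumption and growth
    gamma_G: float = 1.125      # 1/hour
    r_b: float = 0.1            # dimensionless
    G_u: float = 18.0           # mM
    eta_V: float = 20.0         # dimensionless
    gamma_V: float = 20.0       # dimensionless
    V_low: float = -175.0       # mV
    delta_grow: float = 0.0075  # mm/(mM·hour)
    # Acclimation and gating
    eta_K: float = 30.0         # 1/hour
    alpha: float = 5.0          # 1/hour
    beta: float = 2.5           # 1/hour
    m: float = 2.0              # Hill exponent (gate opening)
    G_l: float = 10.0           # mM
    # Reversal potentials
    V_K0: float = -380.0        # mV
    V_L0: float = -156.0        # mV
    delta_K: float = 1.0        # mV/mM
    delta_L: float = 60.0       # mV/mM
    # Reporters
    alpha_T: float = 20.0       # mM/hour
    g_T: float = 0.3            # 1/mV (enters an exponent of a voltage)
    V_0T: float = -170.0        # mV
    gamma_T: float = 10.0       # 1/hour
    alpha_A: float = 0.5        # 1/hour
    gamma_A: float = 1.0        # 1/hour
    # Not tabulated in the source
    K_max: float = 300.0        # mM, pump threshold on internal potassium
    mu: float = 1.0             # fluid viscosity, arbitrary consistent units
    u0: float = 90.0            # mm/hour, inlet centerline speed (2D)
    # Bookkeeping
    units: str = field(default=PAPER_UNITS, compare=False)

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        return replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "units"}


_FIELD_NAMES = frozenset(f.name for f in fields(ParameterSet)) - {"units"}

# Invariant groups
_POSITIVE = (
    "D_G", "D_K", "D_G_fl", "D_K_fl", "G0", "K0", "delta_G", "G_max", "F",
    "g_K", "g_L", "gamma_K", "B_L", "gamma_G", "G_u", "eta_V", "gamma_V",
    "delta_grow", "eta_K", "alpha", "beta", "m", "G_l", "delta_K", "delta_L",
    "alpha_T", "g_T", "gamma_T", "alpha_A", "gamma_A", "K_max", "mu", "u0",
)


def _validate(p: ParameterSet) -> None:
    violations = []
    for name in _POSITIVE:
        v = getattr(p, name)
        if not (v > 0.0):
            violations.append(f"{name} must be strictly positive, got {v!r}")
    if not (0.0 <= p.r_b <= 1.0):
        violations.append(f"r_b must lie in [0, 1], got {p.r_b!r}")
    for name in _FIELD_NAMES:
        if not math.isfinite(getattr(p, name)):
            violations.append(f"{name} must be finite")
    if violations:
        raise ValidationError("; ".join(sorted(violations)))


def load_parameters(
    overrides: dict[str, float] | None = None,
    unit_system_of_overrides: str = PAPER_UNITS,
) -> ParameterSet:
    """Defaults with ``overrides`` applied, validated and normalized.

    Parameters
    ----------
    overrides
        Mapping from parameter name (ASCII names as in :class:`ParameterSet`)
        to value, expressed in ``unit_system_of_overrides``.
    unit_system_of_overrides
        ``"paper"`` or ``"internal"``.

    Returns
    -------
    ParameterSet
        In internal units ({mm, hour, mM, mV}).
    """
    overrides = dict(overrides or {})
    if unit_system_of_overrides not in (PAPER_UNITS, INTERNAL_UNITS):
        raise ConfigurationError(
            f"unknown unit system {unit_system_of_overrides!r}")
    unknown = set(overrides) - _FIELD_NAMES
    if unknown:
        names = ", ".join(sorted(unknown))
        raise ConfigurationError(
            f"unknown parameter name(s): {names}; "
            f"valid names are {', '.join(sorted(_FIELD_NAMES))}")
    for k, v in overrides.items():
        if not isinstance(v, (int, float)) or not math.isfinite(float(v)):
            raise ConfigurationError(f"parameter {k} has non-finite value {v!r}")
        overrides[k] = float(v)

    base = ParameterSet()
    if unit_system_of_overrides == INTERNAL_UNITS:
        base = normalize_units(base)
    p = base.with_overrides(**overrides)
    _validate(p)
    if p.units == PAPER_UNITS:
        p = normalize_units(p)
    return p


def normalize_units(p: ParameterSet) -> ParameterSet:
    """Convert a paper-unit set to the internal {mm, hour, mM, mV} system.

    Only the four diffusivities change (mm²/day → mm²/hour, ÷24); every other
    tabulated quantity is already per-hour/mm/mM/mV.
    """
    if p.units == INTERNAL_UNITS:
        return p
    conv = {name: getattr(p, name) / 24.0 for name in _DIFFUSIVITY_FIELDS}
    return replace(p, units=INTERNAL_UNITS, **conv)


def denormalize_units(p: ParameterSet) -> ParameterSet:
    """Inverse of :func:`normalize_units` (exact round-trip)."""
    if p.units == PAPER_UNITS:
        return p
    conv = {name: getattr(p, name) * 24.0 for name in _DIFFUSIVITY_FIELDS}
    return replace(p, units=PAPER_UNITS, **conv)
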