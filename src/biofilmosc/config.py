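"""Run configuration: YAML parsing, strict validation, defaults.

The configuration schema is strict — unknown keys are errors, with a
nearest-valid-key hint — to protect the parameter-name mapping against
silent typos (``delta_g`` vs ``delta_G`` would otherwise run with the
default and no warning).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field as dfield

import yaml

from .params import ConfigurationError, ParameterSet, load_parameters

__all__ = ["RunConfig", "read_config", "ConfigError"]

MODES = ("simulate1d", "simulate2d", "onset-experiment", "sensitivity",
         "variants")


class ConfigError(ValueError):
    """Configuration file is malformed or inconsistent."""


@dataclass
class RunConfig:
    mode: str = "simulate1d"
    t_end_h: float = 20.0
    dt_max: float = 5.0e-4
    seed: int = 0
    # 1D grid controls
    initial_width_mm: float = 0.2
    dx_mm: float = 0.002
    # 2D grid controls
    cell_mm: tuple[float, float] = (3.0, 3.0)
    h_mm: float = 0.025
    dt_2d: float = 1.0e-3
    shape: dict = dfield(default_factory=lambda: {"name": "wall_half_disc"})
    # variant
    variant: dict = dfield(default_factory=lambda: {"kind": "full"})
    # outputs
    out_dir: str = "out"
    out_dt_h: float = 0.02
    snapshot_every_h: float | None = None
    # mode-specific
    sensitivity_target: str | None = None
    onset_reps: int = 53

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(
                f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.t_end_h < 0:
            raise ConfigError("t_end_h must be non-negative")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")


_TOP_KEYS = ("params", "run", "grid1d", "grid2d", "variant", "output",
             "seed")

_RUN_KEYS = {"mode": "mode", "t_end_h": "t_end_h",
             "sensitivity_target": "sensitivity_target",
             "onset_reps": "onset_reps"}
_GRID1D_KEYS = {"dx_mm": "dx_mm", "dt_max": "dt_max",
                "initial_width_mm": "initial_width_mm"}
_GRID2D_KEYS = {"h_mm": "h_mm", "dt": "dt_2d", "Lx_mm": None, "Ly_mm": None,
                "shape": "shape"}
_OUTPUT_KEYS = {"dir": "out_dir", "out_dt_h": "out_dt_h",
                "snapshot_every_h": "snapshot_every_h"}
_VARIANT_KEYS = ("kind", "mgrow_value", "delta_L_override", "literal_tv",
                 "advect_transport")


def _reject_unknown(d: dict, valid, where: str) -> None:
    for k in d:
        if k not in valid:
            hint = difflib.get_close_matches(str(k), [str(v) for v in valid],
                                             n=1)
            extra = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown key {k!r} in {where}{extra}")


def read_config(path: str) -> tuple[RunConfig, ParameterSet]:
    """Parse a YAML config into (RunConfig, ParameterSet in internal units).

    An empty file yields the full-default configuration.  Parameter
    overrides under ``params`` are in the tabulated (paper) units.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: YAML parse error: {e}") from e
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, path)

    cfg = RunConfig()
    run = raw.get("run") or {}
    _reject_unknown(run, _RUN_KEYS, f"{path}:run")
    for k, attr in _RUN_KEYS.items():
        if k in run:
            setattr(cfg, attr, run[k])
    g1 = raw.get("grid1d") or {}
    _reject_unknown(g1, _GRID1D_KEYS, f"{path}:grid1d")
    for k, attr in _GRID1D_KEYS.items():
        if k in g1:
            setattr(cfg, attr, g1[k])
    g2 = raw.get("grid2d") or {}
    _reject_unknown(g2, _GRID2D_KEYS, f"{path}:grid2d")
    for k, attr in _GRID2D_KEYS.items():
        if k in g2 and attr:
            setattr(cfg, attr, g2[k])
    if "Lx_mm" in g2 or "Ly_mm" in g2:
        cfg.cell_mm = (float(g2.get("Lx_mm", cfg.cell_mm[0])),
                       float(g2.get("Ly_mm", cfg.cell_mm[1])))
    var = raw.get("variant") or {}
    if isinstance(var, str):
        var = {"kind": var}
    _reject_unknown(var, _VARIANT_KEYS, f"{path}:variant")
    cfg.variant = {**cfg.variant, **var}
    out = raw.get("output") or {}
    _reject_unknown(out, _OUTPUT_KEYS, f"{path}:output")
    for k, attr in _OUTPUT_KEYS.items():
        if k in out:
            setattr(cfg, attr, out[k])
    if "seed" in raw and raw["seed"] is not None:
        cfg.seed = int(raw["seed"])
    cfg.validate()

    overrides = raw.get("params") or {}
    if not isinstance(overrides, dict):
        raise ConfigError(f"{path}: params must be a mapping")
    try:
        p = load_parameters(overrides, "paper")
    except ConfigurationError as e:
        # re-raise with a nearest-key hint for typos
        bad = set(overrides) - set(ParameterSet().as_dict())
        if bad:
            k = sorted(bad)[0]
            valid = list(ParameterSet().as_dict())
            lower = {v.lower(): v for v in valid}
            if k.lower() in lower:          # case-only typo
                hint = [lower[k.lower()]]
            else:
                hint = difflib.get_close_matches(k, valid, n=1)
            extra = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(
                f"{path}: unknown parameter {k!r}{extra}") from e
        raise ConfigError(f"{path}: {e}") from e
    return cfg, p
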