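"""Oscillation analysis: onset detection, periods, magnitude, sensitivity.

An oscillation onset is the moment the biofilm's spatial-mean voltage stops
decreasing and begins to increase (a local minimum of mean V).  Events that
occur before the biofilm's doubled width reaches 300 µm are transient
start-up artifacts and are flagged unsustained.  The oscillation magnitude —
max minus min of the mean extracellular potassium over a window — serves as
the proxy for oscillation strength in the parameter-sensitivity protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model1d import OscillationTrace, run_1d
from .params import (ParameterSet, REPORTER_PARAMETERS, denormalize_units,
                     load_parameters)

__all__ = [
    "OnsetEvent", "SensitivityResult", "AnalysisError",
    "detect_onsets", "oscillation_magnitude", "period_by_size",
    "onset_experiment", "sensitivity", "wave_speed_from_snapshots",
]


class AnalysisError(ValueError):
    """The trace is unusable for the requested analysis."""


@dataclass(frozen=True)
class OnsetEvent:
    """A local minimum of mean voltage: the start of one oscillation."""

    time_h: float
    size_at_onset_um: float   # doubled width, µm
    sustained: bool


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    baseline_magnitude_mM: float
    derivative: float          # dO/dp, paper units of p
    percent_per_10pct: float   # dO/dp * 0.1|p|/O * 100


def detect_onsets(trace: OscillationTrace,
                  min_doubled_width_um: float = 300.0,
                  eps_V: float = 0.5,
                  guard_h: float = 0.5) -> list[OnsetEvent]:
    """Local minima of mean voltage, with a noise guard.

    A sample qualifies as an onset if it is a local minimum of the mean-V
    series (first sample of a plateau for flat runs) and the series drops by
    at least ``eps_V`` over the preceding ``guard_h`` hours and rises by at
    least ``eps_V`` over the following ``guard_h`` hours.  Events whose
    doubled width (2·width·1000 µm) is below ``min_doubled_width_um`` are
    flagged unsustained.
    """
    t = np.asarray(trace.time_h, dtype=float)
    v = np.asarray(trace.mean_V_mV, dtype=float)
    if len(t) < 3:
        raise AnalysisError("trace too short for onset detection")
    if np.any(np.diff(t) <= 0):
        raise AnalysisError("trace time must be strictly increasing")

    events: list[OnsetEvent] = []
    for i in range(1, len(v) - 1):
        if not (v[i] < v[i - 1] or (v[i] == v[i - 1] and v[i] < v[i + 1])):
            continue
        if v[i] == v[i - 1]:
            continue  # plateau: only its first sample can qualify
        # next strictly different sample must be higher
        j = i + 1
        while j < len(v) and v[j] == v[i]:
            j += 1
        if j >= len(v) or v[j] < v[i]:
            continue
        # noise guard over +-guard_h
        pre = v[(t >= t[i] - guard_h) & (t <= t[i])]
        post = v[(t >= t[i]) & (t <= t[i] + guard_h)]
        if pre.max() - v[i] < eps_V or post.max() - v[i] < eps_V:
            continue
        size_um = 2.0 * trace.width_mm[i] * 1000.0
        events.append(OnsetEvent(
            time_h=float(t[i]), size_at_onset_um=float(size_um),
            sustained=bool(size_um >= min_doubled_width_um)))
    return events


def oscillation_magnitude(mean_K: np.ndarray,
                          time_h: np.ndarray | None = None,
                          window: tuple[float, float] | None = None) -> float:
    """Max minus min of the mean-potassium series over a window, mM."""
    k = np.asarray(mean_K, dtype=float)
    if window is not None:
        if time_h is None:
            raise AnalysisError("a window requires the time axis")
        t = np.asarray(time_h, dtype=float)
        k = k[(t >= window[0]) & (t <= window[1])]
    if k.size == 0:
        raise AnalysisError("empty window for oscillation magnitude")
    return float(k.max() - k.min())


def period_by_size(events: list[OnsetEvent]) -> list[tuple[float, float]]:
    """(size, period) pairs between consecutive sustained onsets.

    The period between two consecutive sustained onsets is attributed to the
    size at the later onset.  Fewer than two sustained events yield an empty
    list.
    """
    sustained = [e for e in events if e.sustained]
    out = []
    for prev, cur in zip(sustained[:-1], sustained[1:]):
        out.append((cur.size_at_onset_um, cur.time_h - prev.time_h))
    return out


@dataclass
class OnsetExperimentResult:
    onset_sizes_um: np.ndarray      # doubled width at first sustained onset
    initial_widths_um: np.ndarray   # per-replicate initial width
    censored: int                   # replicates with no sustained onset

    @property
    def mean_onset_size_um(self) -> float:
        return float(np.mean(self.onset_sizes_um))


def onset_experiment(p: ParameterSet,
                     n_reps: int = 53,
                     base_width_um: float = 70.0,
                     jitter_um: float = 25.0,
                     t_end: float = 40.0,
                     seed: int | None = 0,
                     **run_kwargs) -> OnsetExperimentResult:
    """Replicate 1D runs measuring the size at the first sustained onset.

    Initial width is uniform on base ± jitter µm (the only stochastic
    element of the model).  Replicates that never reach a sustained onset
    before ``t_end`` are counted as censored and excluded from the mean.
    """
    if n_reps < 1:
        raise AnalysisError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    widths = base_width_um + rng.uniform(-jitter_um, jitter_um, size=n_reps)
    sizes, inits = [], []
    censored = 0
    for w_um in widths:
        trace = run_1d(w_um / 1000.0, p, t_end, **run_kwargs)
        events = [e for e in detect_onsets(trace) if e.sustained]
        if events:
            sizes.append(events[0].size_at_onset_um)
            inits.append(w_um)
        else:
            censored += 1
    return OnsetExperimentResult(
        onset_sizes_um=np.array(sizes), initial_widths_um=np.array(inits),
        censored=censored)


def sensitivity(p: ParameterSet, parameter_name: str,
                h: float = 0.001,
                start_width_um: float = 300.0,
                horizon_h: float = 20.0,
                baseline_O: float | None = None,
                objective=None,
                **run_kwargs) -> SensitivityResult:
    """Forward-difference sensitivity of the oscillation magnitude.

    The objective O is the magnitude (max − min) of the spatial-mean
    extracellular potassium over a ``horizon_h``-hour run started at
    ``start_width_um`` µm.  The parameter is perturbed by the absolute step
    ``h`` in its own tabulated (paper) units; the reported percentage is
    dO/dp · 0.1·|p| / O · 100, the percent change of O for a 10% change of p.

    ``objective`` may replace the default simulation objective with any
    callable ``ParameterSet -> float`` (used to verify the finite-difference
    protocol against closed-form objectives).
    """
    if parameter_name in REPORTER_PARAMETERS:
        raise AnalysisError(
            f"{parameter_name} is a reporter-only parameter; the reporters "
            "do not feed back on the oscillation dynamics")
    paper = denormalize_units(p).as_dict()
    if parameter_name not in paper:
        raise AnalysisError(f"unknown parameter {parameter_name!r}")

    if objective is None:
        def objective(params: ParameterSet) -> float:
            trace = run_1d(start_width_um / 1000.0, params, horizon_h,
                           **run_kwargs)
            return oscillation_magnitude(trace.mean_K_mM, trace.time_h,
                                         window=(0.0, horizon_h))

    O = objective(p) if baseline_O is None else baseline_O
    p_val = paper[parameter_name]
    pert = load_parameters({**paper, parameter_name: p_val + h})
    O_pert = objective(pert)
    dOdp = (O_pert - O) / h
    if O == 0.0:
        raise AnalysisError(
            "baseline oscillation magnitude is zero; percent undefined")
    percent = dOdp * 0.1 * abs(p_val) / O * 100.0
    return SensitivityResult(parameter=parameter_name,
                             baseline_magnitude_mM=O,
                             derivative=dOdp,
                             percent_per_10pct=percent)


def wave_speed_from_snapshots(times_h, K_snaps, inside, h_mm,
                              window: tuple[float, float]):
    """Speed of the travelling potassium crest from field snapshots, µm/min.

    For every biofilm cell the time of its extracellular-potassium maximum
    within ``window`` is found; regressing each cell's distance from the
    wave initiation point (the cell with the earliest crest) on its crest
    time gives the crest propagation speed as the slope.  Cells whose
    maximum falls on the window edge carry no timing information and are
    excluded.

    Returns ``(speed_um_per_min, r_value, n_cells)``.
    """
    from scipy.stats import linregress
    from scipy import ndimage

    t = np.asarray(times_h, dtype=float)
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 5:
        raise AnalysisError("too few snapshots inside the wave window")
    tw = t[sel]
    Kw = np.asarray(K_snaps)[sel][:, inside].astype(float)
    t_crest = tw[np.argmax(Kw, axis=0)]
    interior = (t_crest > tw[0] + 1e-9) & (t_crest < tw[-1] - 1e-9)
    if interior.sum() < 5:
        raise AnalysisError("no interior potassium crest in the window")

    ny, nx = inside.shape
    X, Y = np.meshgrid((np.arange(nx) + 0.5) * h_mm,
                       (np.arange(ny) + 0.5) * h_mm)
    xi, yi = X[inside], Y[inside]
    i0 = np.argmin(np.where(interior, t_crest, np.inf))
    dist = np.hypot(xi - xi[i0], yi - yi[i0])
    res = linregress(t_crest[interior], dist[interior])
    speed = res.slope * 1000.0 / 60.0   # mm/h -> µm/min
    return float(speed), float(res.rvalue), int(interior.sum())
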