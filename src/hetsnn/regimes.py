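"""Dynamical-regime classification and fold/Hopf boundary detection.

A single-cell-type population can be monostable (quiescent or active),
bistable (stable node + stable focus), or synchronously oscillatory.
Classification integrates the mean-field equations from two initial
conditions (quiescent and excited) and inspects the settled rate trace:
sustained oscillation cycles mark the oscillatory regime, distinct
steady rates mark bistability. Fold and Hopf bifurcations can also be
located directly from simulated rate traces under a slow input ramp,
the same heuristic used to validate mean-field predictions against
spiking networks: a fold is the input at which the ramped rate crosses
rT = 10 Hz, and a Hopf interval is the input range sustaining at least
5 cycles of >= 10 Hz trough-to-peak amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .meanfield import (MeanFieldBlowupError, MeanFieldState, PopulationGraph,
                        integrate_mf, single_population_graph)
from .params import NeuronTypeParams

__all__ = [
    "BifDetectConfig",
    "RegimeMap",
    "classify_mf_regime",
    "classify_graph_regime",
    "map_regimes",
    "detect_fold_by_ramp",
    "detect_hopf_by_ramp",
    "mf_ramp_trace",
    "snn_ramp_trace",
]

LABELS = ("quiescent_mono", "active_mono", "bistable", "oscillatory")


@dataclass(frozen=True)
class BifDetectConfig:
    """Thresholds of the rate-trace bifurcation heuristics (Hz)."""

    rate_threshold: float = 10.0      # rT: quiescent/persistent boundary
    osc_amplitude_min: float = 10.0   # trough-to-peak amplitude per cycle
    min_cycles: int = 5
    ramp_rate: float = 0.01           # pA/ms, default slow ramp
    settle_time: float = 2000.0       # ms discarded before classification
    analysis_time: float = 1000.0     # ms window used for classification

    def __post_init__(self) -> None:
        if min(self.rate_threshold, self.osc_amplitude_min, self.ramp_rate,
               self.settle_time, self.analysis_time) <= 0 or self.min_cycles <= 0:
            raise ValueError("all detection parameters must be positive")


def _cycle_amplitudes(trace_hz: np.ndarray, min_prominence: float):
    """(peak indices, trough-to-peak amplitude per cycle).

    A cycle is a detected peak; its amplitude is the rise from the
    deepest point since the previous peak (or window start).
    """
    peaks, _ = find_peaks(trace_hz, prominence=min_prominence)
    amps = np.empty(len(peaks))
    prev = 0
    for i, pk in enumerate(peaks):
        amps[i] = trace_hz[pk] - trace_hz[prev:pk + 1].min()
        prev = pk
    return peaks, amps


def _count_cycles(trace_hz: np.ndarray, config: BifDetectConfig) -> int:
    _, amps = _cycle_amplitudes(trace_hz, config.osc_amplitude_min / 2)
    return int(np.sum(amps >= config.osc_amplitude_min))


def _excited_state(params: NeuronTypeParams, r: float = 0.1) -> MeanFieldState:
    """Self-consistent high-activity guess near the depolarized branch."""
    v = params.vtheta_bar
    return MeanFieldState(
        r=r, v=v, u=params.b * (v - params.vr) + params.tau_u * params.kappa * r,
        s=params.tau_s * params.J * r)


def classify_graph_regime(
    graph: PopulationGraph,
    I: np.ndarray,
    config: BifDetectConfig = BifDetectConfig(),
    observe_pop: int = 0,
    dt: float = 0.01,
) -> str:
    """Regime label of one population inside a (possibly coupled) graph."""
    duration = config.settle_time + config.analysis_time
    quiescent = [MeanFieldState(0.0, p.vr, 0.0, 0.0) for p, _ in graph.populations]
    excited = [_excited_state(p) for p, _ in graph.populations]

    steady = []
    for init in (quiescent, excited):
        # nearly homogeneous populations produce extremely sharp rate
        # spikes; refine the Euler step when the default step is unstable
        traj = None
        for dt_try in (dt, dt / 5, dt / 25):
            try:
                traj = integrate_mf(graph, I, duration, dt=dt_try, init=init,
                                    record_dt=1.0)
                break
            except MeanFieldBlowupError:
                continue
        if traj is None:
            raise MeanFieldBlowupError(
                f"mean-field integration unstable down to dt={dt / 25}")
        tr = traj[traj.population == observe_pop]
        win = tr[tr.time_ms >= config.settle_time]
        r_hz = win["r"].to_numpy() * 1e3
        if _count_cycles(r_hz, config) >= config.min_cycles:
            return "oscillatory"
        steady.append(r_hz[-min(len(r_hz), 200):].mean())

    if abs(steady[0] - steady[1]) > config.rate_threshold:
        return "bistable"
    r_ss = float(np.mean(steady))
    return "active_mono" if r_ss > config.rate_threshold else "quiescent_mono"


def classify_mf_regime(
    params: NeuronTypeParams,
    delta_v: float,
    I: float,
    config: BifDetectConfig = BifDetectConfig(),
    dt: float = 0.01,
) -> str:
    """Regime label of a lone population at heterogeneity ``delta_v``."""
    graph = single_population_graph(params, delta_v)
    return classify_graph_regime(graph, np.array([I]), config, 0, dt)


@dataclass
class RegimeMap:
    """Labels over an (input, heterogeneity) grid plus regime boundaries."""

    input_grid: np.ndarray
    delta_grid: np.ndarray
    labels: np.ndarray                       # (n_delta, n_input) of str
    boundaries: list = field(default_factory=list)  # (delta, I_lo, I_hi, kind)

    def band_width(self, label: str, delta: float) -> float:
        """Refined input-width of the contiguous ``label`` band at ``delta``.

        Uses the bisection-refined boundaries when available, otherwise
        counts grid cells times the grid spacing.
        """
        for d, lo, hi, kind in self.boundaries:
            if kind == label and np.isclose(d, delta):
                return hi - lo
        row = self.labels[np.argmin(np.abs(self.delta_grid - delta))]
        if len(self.input_grid) < 2:
            return 0.0
        dI = np.mean(np.diff(self.input_grid))
        return float(np.sum(row == label) * dI)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.delta_grid):
            for j, I in enumerate(self.input_grid):
                rows.append({"input_pa": I, "delta_v": d, "label": self.labels[i, j]})
        return pd.DataFrame(rows)


def map_regimes(
    model: NeuronTypeParams | PopulationGraph,
    input_grid: np.ndarray,
    delta_grid: np.ndarray,
    config: BifDetectConfig = BifDetectConfig(),
    dt: float = 0.01,
    drive_pop: int = 0,
    delta_pop: int = 0,
    observe_pop: int = 0,
    base_I: np.ndarray | None = None,
    refine_steps: int = 3,
) -> RegimeMap:
    """Classify every (delta_v, I) grid cell and refine band boundaries.

    For a :class:`PopulationGraph`, ``delta_grid`` varies the
    heterogeneity of ``delta_pop``, the swept input is added to
    ``drive_pop`` on top of ``base_I``, and classification observes
    ``observe_pop``.
    """
    input_grid = np.asarray(input_grid, dtype=float)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if input_grid.size == 0 or delta_grid.size == 0:
        raise ValueError("grids must be non-empty")

    def classify(delta: float, I: float) -> str:
        if isinstance(model, PopulationGraph):
            pops = list(model.populations)
            pops[delta_pop] = (pops[delta_pop][0], delta)
            g = PopulationGraph(pops, model.synapses)
            I_vec = np.zeros(len(pops)) if base_I is None else np.array(base_I, dtype=float)
            I_vec[drive_pop] += I
            return classify_graph_regime(g, I_vec, config, observe_pop, dt)
        return classify_mf_regime(model, delta, I, config, dt)

    labels = np.empty((len(delta_grid), len(input_grid)), dtype=object)
    for i, d in enumerate(delta_grid):
        for j, I in enumerate(input_grid):
            labels[i, j] = classify(d, I)

    boundaries = []
    for i, d in enumerate(delta_grid):
        row = labels[i]
        for label in ("bistable", "oscillatory"):
            inside = row == label
            if not inside.any():
                continue
            j_first = int(np.argmax(inside))
            j_last = int(len(row) - 1 - np.argmax(inside[::-1]))
            lo = _bisect_edge(classify, d, input_grid, j_first, -1, label, refine_steps)
            hi = _bisect_edge(classify, d, input_grid, j_last, +1, label, refine_steps)
            boundaries.append((float(d), lo, hi, label))
    return RegimeMap(input_grid=input_grid, delta_grid=delta_grid,
                     labels=labels, boundaries=boundaries)


def _bisect_edge(classify, delta, input_grid, j_in, direction, label, steps):
    """Bisect the regime edge between grid cell j_in and its neighbor."""
    j_out = j_in + direction
    if j_out < 0 or j_out >= len(input_grid):
        return float(input_grid[j_in])
    a, b = float(input_grid[j_in]), float(input_grid[j_out])
    for _ in range(steps):
        mid = 0.5 * (a + b)
        if classify(delta, mid) == label:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def detect_fold_by_ramp(
    rate_trace_hz: np.ndarray,
    input_trace: np.ndarray,
    config: BifDetectConfig = BifDetectConfig(),
) -> float | None:
    """Input value at the first rT-crossing of a slowly ramped rate.

    An upward input ramp detects the upward rate crossing (quiescent
    branch annihilated at the fold); a downward ramp detects the
    downward crossing.
    """
    r = np.asarray(rate_trace_hz, dtype=float)
    I = np.asarray(input_trace, dtype=float)
    if r.shape != I.shape:
        raise ValueError("rate and input traces must be aligned")
    rT = config.rate_threshold
    upward = I[-1] >= I[0]
    if upward:
        above = r >= rT
        if not above.any() or above.all():
            return None
        idx = int(np.argmax(above))
    else:
        below = r <= rT
        if not below.any() or below.all():
            return None
        idx = int(np.argmax(below))
    if idx == 0:
        return None
    # linear interpolation between the bracketing samples
    r0, r1 = r[idx - 1], r[idx]
    frac = 0.0 if r1 == r0 else (rT - r0) / (r1 - r0)
    return float(I[idx - 1] + frac * (I[idx] - I[idx - 1]))


def detect_hopf_by_ramp(
    rate_trace_hz: np.ndarray,
    input_trace: np.ndarray,
    config: BifDetectConfig = BifDetectConfig(),
) -> tuple[float, float] | None:
    """Maximal input interval sustaining qualifying oscillation cycles.

    Scans the ramped rate trace for cycles of trough-to-peak amplitude
    >= osc_amplitude_min; the longest run of consecutive qualifying
    cycles (at least min_cycles of them) marks the oscillatory regime,
    and the input values at its first and last cycle are returned as the
    Hopf bifurcation estimates.
    """
    r = np.asarray(rate_trace_hz, dtype=float)
    I = np.asarray(input_trace, dtype=float)
    if r.shape != I.shape:
        raise ValueError("rate and input traces must be aligned")
    peaks, amps = _cycle_amplitudes(r, config.osc_amplitude_min / 2)
    if len(peaks) == 0:
        return None
    ok = amps >= config.osc_amplitude_min
    best = None
    start = None
    for i in range(len(peaks) + 1):
        if i < len(peaks) and ok[i]:
            if start is None:
                start = i
        else:
            if start is not None:
                run = (start, i - 1)
                if best is None or run[1] - run[0] > best[1] - best[0]:
                    best = run
                start = None
    if best is None or best[1] - best[0] + 1 < config.min_cycles:
        return None
    return float(I[peaks[best[0]]]), float(I[peaks[best[1]]])


def mf_ramp_trace(
    params: NeuronTypeParams,
    delta_v: float,
    I_start: float,
    I_stop: float,
    config: BifDetectConfig = BifDetectConfig(),
    dt: float = 0.01,
    from_excited: bool = False,
) -> pd.DataFrame:
    """Mean-field rate response to a slow linear input ramp.

    Returns (time_ms, input_pa, rate_hz) at 1 ms sampling after an
    initial settle period at ``I_start``.
    """
    graph = single_population_graph(params, delta_v)
    ramp_dur = abs(I_stop - I_start) / config.ramp_rate
    settle = config.settle_time
    duration = settle + ramp_dur
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    I_t = np.where(t < settle, I_start,
                   I_start + (I_stop - I_start) * (t - settle) / ramp_dur)[None, :]
    init = [_excited_state(params)] if from_excited else None
    traj = integrate_mf(graph, I_t, duration, dt=dt, init=init, record_dt=1.0)
    tr = traj[traj.population == 0].reset_index(drop=True)
    tt = tr["time_ms"].to_numpy()
    I_rec = np.where(tt < settle, I_start,
                     I_start + (I_stop - I_start) * np.minimum(tt - settle, ramp_dur) / ramp_dur)
    out = pd.DataFrame({"time_ms": tt, "input_pa": I_rec,
                        "rate_hz": tr["r"].to_numpy() * 1e3})
    return out[out.time_ms >= settle].reset_index(drop=True)


def snn_ramp_trace(
    params: NeuronTypeParams,
    thresholds: np.ndarray,
    coupling,
    I_start: float,
    I_stop: float,
    config: BifDetectConfig = BifDetectConfig(),
    dt: float = 0.01,
    settle: float = 500.0,
    smooth_sigma_ms: float = 10.0,
) -> pd.DataFrame:
    """Spiking-network rate response to a slow linear input ramp.

    The 1 ms-binned population rate is smoothed with a Gaussian kernel
    (SD ``smooth_sigma_ms``) to suppress finite-size spiking noise
    before bifurcation detection.
    """
    from .snn import StimulusProtocol, StimulusSegment, run_snn, population_rate

    ramp_dur = abs(I_stop - I_start) / config.ramp_rate
    duration = settle + ramp_dur
    stim = StimulusProtocol(
        baseline_current=I_start,
        segments=(StimulusSegment(settle, duration, I_stop - I_start,
                                  waveform="ramp"),))
    res = run_snn(params, thresholds, coupling, stim, duration=duration,
                  max_rate_per_neuron=1.0)
    pr = population_rate(res.raster, 1.0)
    pr = pr[pr.time_ms >= settle].reset_index(drop=True)
    rate_hz = gaussian_filter1d(pr["rate_hz"].to_numpy(), smooth_sigma_ms,
                                mode="nearest")
    tt = pr["time_ms"].to_numpy()
    I_rec = I_start + (I_stop - I_start) * np.minimum(tt - settle, ramp_dur) / ramp_dur
    return pd.DataFrame({"time_ms": tt, "input_pa": I_rec, "rate_hz": rate_hz})
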