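"""Spiking-network simulation of Izhikevich neurons with quenched disorder.

The network follows the Izhikevich quadratic membrane equation with a
shared (global) recovery variable per population and exponentially
filtered synapses. A neuron spikes when its potential reaches the
cutoff ``vp`` and is reset to ``v0``; each spike of neuron j increments
the synaptic activation of its postsynaptic targets by the coupling
weight J_ij. Integration is explicit Euler at a default step of
0.01 ms. Rates are handled in spikes/ms internally; helper outputs
provide Hz-scaled copies at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import _kernels
from .connectivity import CouplingMatrix
from .params import NeuronTypeParams

__all__ = [
    "IntegratorConfig",
    "StimulusSegment",
    "StimulusProtocol",
    "SpikeRaster",
    "SNNState",
    "SNNResult",
    "default_integrator",
    "run_snn",
    "run_snn_multi",
    "population_rate",
    "smooth_single_neuron_rates",
]

_SEG_KINDS = {"step": _kernels.SEG_STEP, "ramp": _kernels.SEG_RAMP,
              "sinusoid": _kernels.SEG_SINUSOID}


@dataclass(frozen=True)
class IntegratorConfig:
    """Euler integration settings.

    ``vp``/``v0`` are the spike cutoff and reset potentials. The
    mean-field reduction assumes the symmetric limit vp -> +inf,
    v0 -> -inf about the vertex of the membrane quadratic; the defaults
    produced by :func:`default_integrator` use large symmetric values.
    """

    dt: float = 0.01
    vp: float = 200.0
    v0: float = -300.0
    u_mode: str = "global"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.u_mode not in ("global", "per_neuron"):
            raise ValueError("u_mode must be 'global' or 'per_neuron'")


def default_integrator(params: NeuronTypeParams, dt: float = 0.01,
                       u_mode: str = "global") -> IntegratorConfig:
    """vp = vtheta_bar + 240 mV; v0 mirrored about the quadratic vertex."""
    vp = params.vtheta_bar + 240.0
    v0 = (params.vr + params.vtheta_bar) - vp
    return IntegratorConfig(dt=dt, vp=vp, v0=v0, u_mode=u_mode)


@dataclass(frozen=True)
class StimulusSegment:
    t_on: float
    t_off: float
    amplitude: float
    waveform: str = "step"          # step | ramp | sinusoid
    frequency: float = 0.0          # Hz, sinusoid only
    target: np.ndarray | None = None  # bool mask over neurons; None = all

    def __post_init__(self) -> None:
        if self.t_on >= self.t_off:
            raise ValueError("t_on must precede t_off")
        if self.waveform not in _SEG_KINDS:
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class StimulusProtocol:
    """Baseline current (pA) plus additive time-windowed segments."""

    baseline_current: float = 0.0
    segments: tuple[StimulusSegment, ...] = ()

    def current_trace(self, times: np.ndarray, neuron: int | None = None,
                      n_neurons: int = 1) -> np.ndarray:
        """Evaluate I(t) on a time grid, for one neuron or the full-mask drive."""
        out = np.full_like(np.asarray(times, dtype=float), self.baseline_current)
        for seg in self.segments:
            if seg.target is not None and neuron is not None and not seg.target[neuron]:
                continue
            active = (times >= seg.t_on) & (times < seg.t_off)
            if seg.waveform == "step":
                amp = seg.amplitude
                out[active] += amp
            elif seg.waveform == "ramp":
                out[active] += seg.amplitude * (
                    times[active] - seg.t_on) / (seg.t_off - seg.t_on)
            else:
                out[active] += seg.amplitude * np.sin(
                    2 * np.pi * seg.frequency * (times[active] - seg.t_on) * 1e-3)
        return out


@dataclass
class SpikeRaster:
    """Recorded spikes: parallel arrays of neuron ids and times (ms)."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    def __len__(self) -> int:
        return len(self.times)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron_ids, "time_ms": self.times})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_neurons: int, duration: float) -> "SpikeRaster":
        df = pd.read_csv(path)
        return cls(df["neuron_id"].to_numpy(np.int64),
                   df["time_ms"].to_numpy(float), n_neurons, duration)


@dataclass
class SNNState:
    """Final (or initial) network state."""

    v: np.ndarray              # (N,) mV
    u: np.ndarray              # (n_pop,) pA for global mode, (N,) per-neuron
    s: np.ndarray              # (n_types, N) dimensionless
    t: float = 0.0

    def copy(self) -> "SNNState":
        return SNNState(self.v.copy(), self.u.copy(), self.s.copy(), self.t)


@dataclass
class SNNResult:
    raster: SpikeRaster
    state: SNNState
    trace: pd.DataFrame        # time, per-pop mean v, u, mean s (subsampled)
    rate: pd.DataFrame         # time, per-pop rate in spikes/ms and Hz (1 ms bins)


class SimulationBlowupError(RuntimeError):
    pass


def _segments_to_arrays(protocol: StimulusProtocol, n: int):
    segs = protocol.segments
    n_seg = len(segs)
    ton = np.array([s.t_on for s in segs], dtype=float)
    toff = np.array([s.t_off for s in segs], dtype=float)
    amp = np.array([s.amplitude for s in segs], dtype=float)
    kind = np.array([_SEG_KINDS[s.waveform] for s in segs], dtype=np.int64)
    freq = np.array([s.frequency for s in segs], dtype=float)
    mask = np.ones((n_seg, n), dtype=np.bool_)
    for j, s_ in enumerate(segs):
        if s_.target is not None:
            m = np.asarray(s_.target)
            if m.dtype != np.bool_:
                mm = np.zeros(n, dtype=np.bool_)
                mm[m] = True
                m = mm
            mask[j] = m
    if n_seg == 0:
        ton = toff = amp = freq = np.zeros(0)
        kind = np.zeros(0, dtype=np.int64)
        mask = np.zeros((0, n), dtype=np.bool_)
    return ton, toff, amp, kind, freq, mask


def run_snn_multi(
    populations: list[tuple[NeuronTypeParams, np.ndarray]],
    synapses: list[tuple[int, int, CouplingMatrix, float, float, float]],
    stimuli: list[StimulusProtocol],
    integ: IntegratorConfig,
    duration: float,
    init: SNNState | None = None,
    record_dt: float = 1.0,
    rate_bin: float = 1.0,
    max_rate_per_neuron: float = 1.0,
) -> SNNResult:
    """Simulate a network of one or more interacting populations.

    Parameters
    ----------
    populations
        ``(params, thresholds)`` per population; neuron ids are assigned
        contiguously in order.
    synapses
        ``(pre_pop, post_pop, coupling, g, E, tau_s)`` per synapse type.
        ``coupling.weights[i, j]`` couples presynaptic neuron j (local
        index in ``pre_pop``) to postsynaptic neuron i (local index in
        ``post_pop``).
    stimuli
        One :class:`StimulusProtocol` per population; segment masks are
        over the population's local indices.
    max_rate_per_neuron
        Preallocation budget for the spike buffer, in spikes/ms/neuron.
    """
    n_pop = len(populations)
    sizes = [len(th) for _, th in populations]
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    n = int(offsets[-1])
    pop_of = np.empty(n, dtype=np.int32)
    for p, (lo, hi) in enumerate(zip(offsets[:-1], offsets[1:])):
        pop_of[lo:hi] = p
    pop_count = np.array(sizes, dtype=np.int64)

    def per_neuron(attr):
        return np.concatenate([np.full(sizes[p], getattr(populations[p][0], attr))
                               for p in range(n_pop)])

    vth = np.concatenate([np.asarray(th, dtype=float) for _, th in populations])
    C = per_neuron("C"); k = per_neuron("k"); vr = per_neuron("vr")
    per_pop_params = [pp for pp, _ in populations]
    vp = np.full(n, integ.vp, dtype=float)
    v0 = np.full(n, integ.v0, dtype=float)

    u_per_neuron = integ.u_mode == "per_neuron"
    if u_per_neuron:
        b_u = per_neuron("b"); tau_u = per_neuron("tau_u")
        kappa = per_neuron("kappa"); vr_u = per_neuron("vr")
        n_u = n
    else:
        b_u = np.array([pp.b for pp in per_pop_params])
        tau_u = np.array([pp.tau_u for pp in per_pop_params])
        kappa = np.array([pp.kappa for pp in per_pop_params])
        vr_u = np.array([pp.vr for pp in per_pop_params])
        n_u = n_pop

    # synapse types: out-edge (CSC) structure in global indices
    n_types = len(synapses)
    type_tau = np.array([s[5] for s in synapses]) if n_types else np.zeros(0)
    type_g = np.array([s[3] for s in synapses]) if n_types else np.zeros(0)
    type_E = np.array([s[4] for s in synapses]) if n_types else np.zeros(0)
    edge_indptr = np.zeros((max(n_types, 1), n + 1), dtype=np.int64)
    idx_parts, dat_parts = [], []
    offset = 0
    for m, (pre, post, cm, _, _, _) in enumerate(synapses):
        csc = cm.weights.tocsc()
        indptr = np.zeros(n + 1, dtype=np.int64)
        lo_pre, hi_pre = offsets[pre], offsets[pre + 1]
        indptr[lo_pre + 1: hi_pre + 1] = csc.indptr[1:]
        indptr[hi_pre + 1:] = csc.indptr[-1]
        edge_indptr[m] = indptr + offset
        idx_parts.append(csc.indices.astype(np.int64) + offsets[post])
        dat_parts.append(csc.data.astype(float))
        offset += len(csc.data)
    edge_indices = (np.concatenate(idx_parts) if idx_parts
                    else np.zeros(0, dtype=np.int64))
    edge_data = np.concatenate(dat_parts) if dat_parts else np.zeros(0)

    base_I = np.concatenate([
        np.full(sizes[p], stimuli[p].baseline_current) for p in range(n_pop)])
    seg_rows = []
    for p in range(n_pop):
        ton, toff, amp, kind, freq, mask = _segments_to_arrays(stimuli[p], sizes[p])
        for j in range(len(ton)):
            gm = np.zeros(n, dtype=np.bool_)
            gm[offsets[p]:offsets[p + 1]] = mask[j]
            seg_rows.append((ton[j], toff[j], amp[j], kind[j], freq[j], gm))
    if seg_rows:
        seg_ton = np.array([r[0] for r in seg_rows])
        seg_toff = np.array([r[1] for r in seg_rows])
        seg_amp = np.array([r[2] for r in seg_rows])
        seg_kind = np.array([r[3] for r in seg_rows], dtype=np.int64)
        seg_freq = np.array([r[4] for r in seg_rows])
        seg_mask = np.stack([r[5] for r in seg_rows])
    else:
        seg_ton = seg_toff = seg_amp = seg_freq = np.zeros(0)
        seg_kind = np.zeros(0, dtype=np.int64)
        seg_mask = np.zeros((0, n), dtype=np.bool_)

    if init is None:
        state = SNNState(v=vr.copy(), u=np.zeros(n_u),
                         s=np.zeros((max(n_types, 1), n)), t=0.0)
    else:
        state = init.copy()
        if state.s.shape[0] < max(n_types, 1):
            raise ValueError("initial state has too few synapse-type channels")

    dt = integ.dt
    n_steps = int(round(duration / dt))
    rec_every = max(int(round(record_dt / dt)), 1)
    n_rec = n_steps // rec_every + 1
    rec_v = np.zeros((n_rec, n_pop))
    rec_u = np.zeros((n_rec, n_u))
    rec_s = np.zeros((n_rec, max(n_types, 1)))
    rate_bin_steps = max(int(round(rate_bin / dt)), 1)
    n_bins = int(np.ceil(n_steps / rate_bin_steps))
    rate_counts = np.zeros((n_bins, n_pop), dtype=np.int64)
    max_spikes = int(max_rate_per_neuron * n * duration) + 16
    spike_ids = np.zeros(max_spikes, dtype=np.int64)
    spike_ts = np.zeros(max_spikes)

    status, n_spikes, stop_step = _kernels.snn_euler(
        state.v, state.u, state.s, pop_of, pop_count,
        vth, C, k, vr, vp, v0, b_u, tau_u, kappa, vr_u,
        type_tau, type_g, type_E, edge_indptr, edge_indices, edge_data,
        base_I, seg_ton, seg_toff, seg_amp, seg_kind, seg_freq, seg_mask,
        dt, n_steps, state.t, u_per_neuron, rec_every,
        rec_v, rec_u, rec_s, rate_counts, rate_bin_steps,
        spike_ids, spike_ts)
    if status == _kernels.ERR_NONFINITE:
        raise SimulationBlowupError(
            f"non-finite membrane potential at step {stop_step} "
            f"(t = {state.t + stop_step * dt:.3f} ms); reduce dt")
    if status == _kernels.ERR_OVERFLOW:
        raise SimulationBlowupError(
            f"spike buffer exhausted at step {stop_step}; the network is "
            "firing above the max_rate_per_neuron budget")

    # close the subsampled trace with the final state
    for p in range(n_pop):
        rec_v[-1, p] = state.v[pop_of == p].mean()
    rec_u[-1, :] = state.u[:rec_u.shape[1]]
    rec_s[-1, :] = state.s.mean(axis=1)

    t_start = state.t
    state.t = t_start + duration
    raster = SpikeRaster(
        neuron_ids=spike_ids[:n_spikes].copy(),
        times=spike_ts[:n_spikes].copy() - t_start,
        n_neurons=n, duration=duration)

    rec_t = t_start + np.arange(n_rec) * rec_every * dt
    rec_t[-1] = t_start + duration
    trace = {"time_ms": rec_t}
    for p in range(n_pop):
        trace[f"v_mean_{p}"] = rec_v[:, p]
    for j in range(min(n_u, n_pop) if not u_per_neuron else 0):
        trace[f"u_{j}"] = rec_u[:, j]
    if u_per_neuron:
        trace["u_mean_0"] = rec_u.mean(axis=1)
    for m in range(max(n_types, 1)):
        trace[f"s_mean_{m}"] = rec_s[:, m]
    trace = pd.DataFrame(trace)

    bin_t = t_start + (np.arange(n_bins) + 0.5) * rate_bin_steps * dt
    rate = {"time_ms": bin_t}
    for p in range(n_pop):
        r_ms = rate_counts[:, p] / (pop_count[p] * rate_bin_steps * dt)
        rate[f"rate_{p}"] = r_ms
        rate[f"rate_hz_{p}"] = r_ms * 1e3
    rate = pd.DataFrame(rate)
    return SNNResult(raster=raster, state=state, trace=trace, rate=rate)


def run_snn(
    params: NeuronTypeParams,
    thresholds: np.ndarray,
    coupling: CouplingMatrix,
    stim: StimulusProtocol,
    integ: IntegratorConfig | None = None,
    duration: float = 1000.0,
    init: SNNState | None = None,
    record_dt: float = 1.0,
    max_rate_per_neuron: float = 1.0,
) -> SNNResult:
    """Simulate a single population with recurrent coupling.

    Thin wrapper around :func:`run_snn_multi` with one synapse type
    using the population's own (g, E, tau_s).
    """
    if integ is None:
        integ = default_integrator(params)
    thresholds = np.asarray(thresholds, dtype=float)
    if coupling.n_neurons != len(thresholds):
        raise ValueError("thresholds length must match the coupling matrix")
    return run_snn_multi(
        populations=[(params, thresholds)],
        synapses=[(0, 0, coupling, params.g, params.E, params.tau_s)],
        stimuli=[stim],
        integ=integ,
        duration=duration,
        init=init,
        record_dt=record_dt,
        max_rate_per_neuron=max_rate_per_neuron,
    )


def population_rate(raster: SpikeRaster, bin: float = 1.0) -> pd.DataFrame:
    """Population rate from a raster: counts per bin / (N * bin).

    Returns a frame with the bin centers, the rate in spikes/ms and a
    Hz-scaled copy.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    n_bins = max(int(np.ceil(raster.duration / bin)), 1)
    counts, _ = np.histogram(raster.times, bins=n_bins, range=(0.0, n_bins * bin))
    r_ms = counts / (raster.n_neurons * bin)
    return pd.DataFrame({
        "time_ms": (np.arange(n_bins) + 0.5) * bin,
        "rate": r_ms,
        "rate_hz": r_ms * 1e3,
    })


def smooth_single_neuron_rates(
    raster: SpikeRaster,
    fs: float = 10.0,
    sigma: float = 200.0,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> np.ndarray:
    """Per-neuron smoothed rate matrix (N x T), in spikes per sample.

    Spike trains are binned at ``fs`` samples/ms and convolved with a
    unit-area Gaussian kernel of SD ``sigma`` samples, so each spike
    contributes unit integral (in samples) to its row.
    """
    if fs <= 0 or sigma <= 0:
        raise ValueError("fs and sigma must be positive")
    if t_stop is None:
        t_stop = raster.duration
    n_samp = int(round((t_stop - t_start) * fs))
    out = np.zeros((raster.n_neurons, n_samp))
    sel = (raster.times >= t_start) & (raster.times < t_stop)
    cols = ((raster.times[sel] - t_start) * fs).astype(np.int64)
    cols = np.clip(cols, 0, n_samp - 1)
    np.add.at(out, (raster.neuron_ids[sel], cols), 1.0)
    return gaussian_filter1d(out, sigma=sigma, axis=1, mode="constant", truncate=6.0)
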