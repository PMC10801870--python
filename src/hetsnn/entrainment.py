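"""Entrainment of the mean-field rate dynamics by periodic forcing.

The population input is I(t) = I0 + alpha * sin(2 pi omega t); the
question is over which forcing frequencies the rate fluctuations lock
to the drive. Locking is quantified by the phase-locking value (PLV):
both the forcing and the rate trace are band-passed around the forcing
frequency, instantaneous phases are extracted with the analytic
(Hilbert) signal, and the PLV is |<exp(i (phi_r - phi_f))>|, bounded in
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert

from .meanfield import integrate_mf, single_population_graph
from .params import NeuronTypeParams, preset

__all__ = ["ForcingSpec", "coherence", "forced_rate_trace", "entrainment_map"]


@dataclass(frozen=True)
class ForcingSpec:
    """Sinusoidal forcing on top of a constant baseline drive."""

    I0: float = 60.0          # pA baseline
    alpha: float = 4.0        # pA forcing strength
    omega: float = 5.0        # Hz forcing frequency
    duration: float = 8000.0  # ms simulated
    discard: float = 2000.0   # ms transient removed before scoring

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not (0 <= self.discard < self.duration):
            raise ValueError("discard must lie inside the duration")

    def to_dict(self) -> dict:
        return asdict(self)


def _band_phase(x: np.ndarray, omega_hz: float, fs_hz: float,
                rel_band: float = 0.3) -> np.ndarray:
    lo = max(omega_hz * (1 - rel_band), 1e-3)
    hi = min(omega_hz * (1 + rel_band), 0.49 * fs_hz)
    b, a = butter(2, [lo, hi], btype="bandpass", fs=fs_hz)
    return np.angle(hilbert(filtfilt(b, a, x)))


def coherence(forcing: np.ndarray, rate: np.ndarray, omega: float,
              fs: float = 1.0, rel_band: float = 0.3,
              min_fluctuation: float = 1e-12) -> tuple[float, bool]:
    """Phase-locking value between forcing and rate traces.

    ``omega`` in Hz, ``fs`` in samples/ms. Returns (plv, flagged);
    ``flagged`` is True when the rate trace carries no oscillatory
    component (PLV reported as 0).
    """
    forcing = np.asarray(forcing, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if forcing.shape != rate.shape:
        raise ValueError("traces must have equal length")
    if np.std(rate) < min_fluctuation or np.std(forcing) < min_fluctuation:
        return 0.0, True
    fs_hz = fs * 1e3
    phi_f = _band_phase(forcing, omega, fs_hz, rel_band)
    phi_r = _band_phase(rate, omega, fs_hz, rel_band)
    # drop filter edge transients (two forcing periods each side)
    edge = min(int(2 * fs_hz / omega), len(rate) // 4)
    dphi = (phi_r - phi_f)[edge:len(rate) - edge]
    plv = float(np.abs(np.mean(np.exp(1j * dphi))))
    return plv, False


def forced_rate_trace(params: NeuronTypeParams, delta_v: float,
                      spec: ForcingSpec, dt: float = 0.01,
                      record_dt: float = 1.0) -> pd.DataFrame:
    """Integrate the forced mean-field model; returns (time, forcing, rate)."""
    graph = single_population_graph(params, delta_v)
    n_steps = int(round(spec.duration / dt))
    t = np.arange(n_steps) * dt
    I_t = (spec.I0 + spec.alpha * np.sin(2 * np.pi * spec.omega * t * 1e-3))[None, :]
    traj = integrate_mf(graph, I_t, spec.duration, dt=dt, record_dt=record_dt)
    tr = traj[traj.population == 0].reset_index(drop=True)
    tt = tr["time_ms"].to_numpy()
    out = pd.DataFrame({
        "time_ms": tt,
        "forcing": spec.alpha * np.sin(2 * np.pi * spec.omega * tt * 1e-3),
        "rate_hz": tr["r"].to_numpy() * 1e3,
    })
    return out[out.time_ms >= spec.discard].reset_index(drop=True)


def entrainment_map(
    params: NeuronTypeParams | None = None,
    delta_grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
    omega_grid: np.ndarray | None = None,
    base: ForcingSpec = ForcingSpec(),
    delta_v: float | None = None,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Coherence over (omega, delta_v) or (omega, alpha) grids.

    Exactly one of ``delta_grid`` / ``alpha_grid`` must be given; the
    other axis is fixed by ``base`` (and ``delta_v`` when sweeping
    alpha). Returns tidy rows (omega, delta_v, alpha, coherence,
    flagged).
    """
    if params is None:
        params = preset("rs", kappa_override=100.0)
    if (delta_grid is None) == (alpha_grid is None):
        raise ValueError("give exactly one of delta_grid or alpha_grid")
    if omega_grid is None or len(omega_grid) == 0:
        raise ValueError("omega_grid must be non-empty")
    rows = []
    if delta_grid is not None:
        sweep = [(float(d), base.alpha) for d in delta_grid]
    else:
        if delta_v is None:
            delta_v = params.delta_v
        sweep = [(float(delta_v), float(a)) for a in alpha_grid]
    for d, a in sweep:
        for w in omega_grid:
            spec = ForcingSpec(I0=base.I0, alpha=a, omega=float(w),
                               duration=base.duration, discard=base.discard)
            if a == 0:
                rows.append({"omega": float(w), "delta_v": d, "alpha": a,
                             "coherence": 0.0, "flagged": True})
                continue
            tr = forced_rate_trace(params, d, spec, dt=dt)
            plv, flagged = coherence(tr["forcing"].to_numpy(),
                                     tr["rate_hz"].to_numpy(), float(w))
            rows.append({"omega": float(w), "delta_v": d, "alpha": a,
                         "coherence": plv, "flagged": flagged})
    return pd.DataFrame(rows)
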