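"""Function generation by stimulus-evoked network dynamics.

A ring network held in one of three regimes (asynchronous quiescent,
oscillatory, asynchronous active) is probed with a short pulse at many
onset times; the smoothed post-onset activity of all neurons forms a
feature matrix X (N x T) per trial. A ridge-regression readout
w = y X^T (X X^T + gamma I)^-1 is fit on training onsets and scored by
mean-squared error on held-out onsets. Two summary statistics describe
the reservoir: the participation ratio d = (sum lambda)^2 / sum
lambda^2 of the covariance spectrum (effective dimensionality), and the
trial-to-trial variance q of the T x T ridge response kernel
K = X_a^T (X X^T + gamma I)^-1 X_a, which measures how strongly the
input-output map depends on the intrinsic network state at stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .connectivity import ConnectivitySpec, build_connectivity
from .params import DisorderSpec, NeuronTypeParams, default_truncation, preset, sample_thresholds
from .snn import (SNNState, StimulusProtocol, StimulusSegment,
                  default_integrator, run_snn, smooth_single_neuron_rates)

__all__ = [
    "OnsetProtocol",
    "ResponseSet",
    "ReadoutModel",
    "make_target",
    "collect_responses",
    "fit_readout",
    "predict",
    "test_mse",
    "participation_ratio",
    "response_kernel",
    "kernel_variance",
    "function_generation_sweep",
]


@dataclass(frozen=True)
class OnsetProtocol:
    """Stimulation-onset protocol for reservoir probing."""

    n_onsets: int = 50
    n_train: int = 40
    n_test: int = 10
    burn_in: float = 2000.0       # ms before the first onset
    post_onset: float = 250.0     # ms of response entering X
    onset_span: float = 250.0     # ms; replaced by one cycle if oscillatory
    n_neurons: int = 2000
    coupling_prob: float = 0.2
    ring_exponent: float = 0.75
    pulse_width_frac: float = 0.25  # stimulated fraction of the ring
    pulse_amp: float = 60.0         # pA, suprathreshold on the arc
    pulse_duration: float = 20.0    # ms
    feature_sigma: float = 10.0   # ms, smoothing of single-neuron rates
    feature_fs: float = 1.0       # samples per ms for X

    def __post_init__(self) -> None:
        if self.n_train + self.n_test != self.n_onsets:
            raise ValueError("n_train + n_test must equal n_onsets")


@dataclass
class ResponseSet:
    """Per-onset response matrices and the train/test split."""

    X: list[np.ndarray]           # each (N, T)
    onset_times: np.ndarray       # ms relative to burn-in end
    train_idx: np.ndarray
    test_idx: np.ndarray
    oscillation_period: float | None  # ms, None if asynchronous

    @property
    def X_train(self) -> list[np.ndarray]:
        return [self.X[i] for i in self.train_idx]

    @property
    def X_test(self) -> list[np.ndarray]:
        return [self.X[i] for i in self.test_idx]


@dataclass
class ReadoutModel:
    w: np.ndarray
    gamma: float
    target_id: str = ""


def make_target(kind: str, T: np.ndarray) -> np.ndarray:
    """Target signals on a ms time grid.

    ``product_sines``: sin(2 pi 5 Hz t) * sin(2 pi 20 Hz t).
    ``smoothed_delta``: unit-integral Gaussian (sigma = 15 ms) at 150 ms.
    """
    t = np.asarray(T, dtype=float)  # ms
    if kind == "product_sines":
        return np.sin(2 * np.pi * 5e-3 * t) * np.sin(2 * np.pi * 20e-3 * t)
    if kind == "smoothed_delta":
        sig = 15.0
        y = np.exp(-0.5 * ((t - 150.0) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
        return y
    raise ValueError(f"unknown target kind {kind!r}")


def _default_gamma(X: np.ndarray) -> float:
    """Scale-relative ridge: one tenth of the mean per-neuron feature energy.

    trace(X X^T)/N is the average squared feature magnitude per neuron;
    regularizing at a fixed fraction of it keeps the effective ridge
    strength comparable across network sizes, regimes and heterogeneity
    levels, and guards against fitting trial-specific activity when few
    training trials are available.
    """
    return 0.1 * float(np.einsum("ij,ij->", X, X)) / X.shape[0]


def fit_readout(X_train: list[np.ndarray] | np.ndarray, y: np.ndarray,
                gamma: float | None = None) -> ReadoutModel:
    """Ridge readout w = y X^T (X X^T + gamma I)^-1 on concatenated trials."""
    if isinstance(X_train, list):
        if len(X_train) == 0:
            raise ValueError("need at least one training trial")
        X = np.hstack(X_train)
        y_full = np.tile(np.asarray(y, dtype=float), len(X_train))
    else:
        X = np.asarray(X_train, dtype=float)
        y_full = np.asarray(y, dtype=float)
    if X.shape[1] != y_full.shape[0]:
        raise ValueError("target length must match concatenated trial length")
    if gamma is None:
        gamma = _default_gamma(X)
    G = X @ X.T + gamma * np.eye(X.shape[0])
    try:
        w = np.linalg.solve(G, X @ y_full)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X X^T is singular; use gamma > 0 to regularize") from exc
    return ReadoutModel(w=w, gamma=float(gamma))


def predict(model: ReadoutModel, X: np.ndarray) -> np.ndarray:
    return model.w @ X


def test_mse(model: ReadoutModel, X_test: list[np.ndarray], y: np.ndarray) -> float:
    """Mean over test trials of the MSE between w X and the target."""
    y = np.asarray(y, dtype=float)
    errs = [float(np.mean((predict(model, X) - y) ** 2)) for X in X_test]
    return float(np.mean(errs))


test_mse.__test__ = False  # not a pytest case despite the name


def participation_ratio(X: np.ndarray) -> float:
    """(sum lambda)^2 / sum lambda^2 over covariance eigenvalues of X rows."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        raise ValueError("X has no variance; participation ratio undefined")
    sv = np.linalg.svd(Xc, compute_uv=False)
    lam = sv ** 2
    return float(lam.sum() ** 2 / np.sum(lam ** 2))


def response_kernel(X_trial: np.ndarray, X_train_concat: np.ndarray,
                    gamma: float | None = None) -> np.ndarray:
    """Ridge hat-matrix kernel K = X_a^T (X X^T + gamma I)^-1 X_a (T x T)."""
    Xc = np.asarray(X_train_concat, dtype=float)
    Xa = np.asarray(X_trial, dtype=float)
    if gamma is None:
        gamma = _default_gamma(Xc)
    G = Xc @ Xc.T + gamma * np.eye(Xc.shape[0])
    try:
        return Xa.T @ np.linalg.solve(G, Xa)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X X^T is singular; use gamma > 0 to regularize") from exc


def kernel_variance(K_per_trial: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Trial-difference matrix Q and its summed square q.

    Q_ij is the mean absolute difference of K_ij over unordered trial
    pairs; q = sum_ij Q_ij^2. Use q / T^2 for comparisons across T.
    """
    if len(K_per_trial) < 2:
        raise ValueError("kernel variance needs at least 2 trials")
    Ks = np.stack(K_per_trial)
    n = len(Ks)
    Q = np.zeros_like(Ks[0])
    n_pairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            Q += np.abs(Ks[a] - Ks[b])
            n_pairs += 1
    Q /= n_pairs
    q = float(np.sum(Q ** 2))
    return Q, q


def _measure_period(rate_hz: np.ndarray, min_amp: float = 10.0,
                    smooth_ms: float = 5.0, min_period: float = 20.0) -> tuple[float | None, int | None]:
    """Intrinsic oscillation period (ms @ 1 ms sampling) and last trough.

    The rate trace is smoothed to suppress finite-size spiking noise;
    the network counts as oscillatory only if at least 5 cycles reach
    ``min_amp`` trough-to-peak and the mean trough interval exceeds
    ``min_period`` (adaptation-driven population rhythms are slow).
    """
    sm = gaussian_filter1d(np.asarray(rate_hz, dtype=float), smooth_ms, mode="nearest")
    troughs, _ = find_peaks(-sm, prominence=min_amp / 2)
    peaks, _ = find_peaks(sm, prominence=min_amp / 2)
    if len(troughs) < 3 or len(peaks) < 5:
        return None, None
    amps = []
    for pk in peaks:
        prev = troughs[troughs < pk]
        if len(prev):
            amps.append(sm[pk] - sm[prev[-1]])
    if np.sum(np.asarray(amps) >= min_amp) < 5:
        return None, None
    period = float(np.mean(np.diff(troughs)))
    if period < min_period:
        return None, None
    return period, int(troughs[-1])


def collect_responses(
    params: NeuronTypeParams,
    disorder: DisorderSpec,
    protocol: OnsetProtocol,
    regime_input: float,
    seed: int = 0,
) -> ResponseSet:
    """Simulate all stimulation onsets from a shared initial condition.

    A burn-in run at the regime input establishes the initial state; if
    the settled rate oscillates (>= 10 Hz trough-to-peak), the burn-in
    is extended to end at an oscillation trough and the onsets span one
    intrinsic cycle, otherwise they span ``onset_span`` ms. Per onset,
    the network is advanced from the shared state, pulsed, and the
    Gaussian-smoothed single-neuron rates over the following
    ``post_onset`` ms form the response matrix.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    th_seed, conn_seed, split_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss)
    thresholds = sample_thresholds(replace(disorder, seed=th_seed), protocol.n_neurons)
    coupling = build_connectivity(
        ConnectivitySpec(protocol.n_neurons, "ring_power_law",
                         protocol.coupling_prob, protocol.ring_exponent,
                         seed=conn_seed),
        params.J)
    integ = default_integrator(params)
    stim_base = StimulusProtocol(baseline_current=regime_input)

    burn = run_snn(params, thresholds, coupling, stim_base, integ,
                   duration=protocol.burn_in, max_rate_per_neuron=1.0)
    rate_hz = burn.rate["rate_hz_0"].to_numpy()
    period, last_trough = _measure_period(rate_hz[len(rate_hz) // 2:])
    if period is not None:
        # re-run the burn-in so that it ends exactly at a rate trough
        t_end = float(len(rate_hz) // 2 + last_trough)
        burn = run_snn(params, thresholds, coupling, stim_base, integ,
                       duration=t_end, max_rate_per_neuron=1.0)
        span = period
    else:
        span = protocol.onset_span
    state0 = burn.state

    n_in = max(int(np.ceil(protocol.pulse_width_frac * protocol.n_neurons)), 1)
    mask = np.zeros(protocol.n_neurons, dtype=bool)
    mask[(np.arange(n_in) - n_in // 2) % protocol.n_neurons] = True

    onsets = np.arange(protocol.n_onsets) * span / protocol.n_onsets
    margin = 4.0 * protocol.feature_sigma
    X = []
    for t_on in onsets:
        t0 = state0.t
        stim = StimulusProtocol(
            baseline_current=regime_input,
            segments=(StimulusSegment(t0 + t_on, t0 + t_on + protocol.pulse_duration,
                                      protocol.pulse_amp, target=mask),))
        res = run_snn(params, thresholds, coupling, stim, integ,
                      duration=t_on + protocol.post_onset + margin,
                      init=state0.copy(), max_rate_per_neuron=1.0)
        # smooth with a leading/trailing margin so kernel edges do not
        # bias the response window, then cut to [t_on, t_on + post_onset)
        lead = min(t_on, margin)
        rates = smooth_single_neuron_rates(
            res.raster, fs=protocol.feature_fs,
            sigma=protocol.feature_sigma * protocol.feature_fs,
            t_start=t_on - lead, t_stop=t_on + protocol.post_onset + margin)
        i0 = int(round(lead * protocol.feature_fs))
        n_t = int(round(protocol.post_onset * protocol.feature_fs))
        X.append(rates[:, i0:i0 + n_t])

    rng = np.random.default_rng(split_seed)
    test_idx = np.sort(rng.choice(protocol.n_onsets, size=protocol.n_test, replace=False))
    train_idx = np.setdiff1d(np.arange(protocol.n_onsets), test_idx)
    return ResponseSet(X=X, onset_times=onsets, train_idx=train_idx,
                       test_idx=test_idx, oscillation_period=period)


def function_generation_sweep(
    regime_inputs: list[float],
    delta_grid: list[float],
    protocol: OnsetProtocol,
    seeds: list[int],
    params: NeuronTypeParams | None = None,
    family: str = "lorentzian",
    targets: tuple[str, ...] = ("product_sines", "smoothed_delta"),
) -> pd.DataFrame:
    """Full pipeline per (regime input, delta_v, seed, target).

    Columns: input_pa, delta_v, seed, target, mse, dimensionality,
    kernel_q, kernel_q_norm, oscillation_period.
    """
    if params is None:
        params = preset("rs", kappa_override=100.0)
    low, high = default_truncation(params)
    t_grid = np.arange(int(protocol.post_onset)) / protocol.feature_fs
    rows = []
    for I in regime_inputs:
        for delta in delta_grid:
            spec = DisorderSpec(family, params.vtheta_bar, float(delta), low, high)
            for seed in seeds:
                rs_set = collect_responses(params, spec, protocol, float(I), int(seed))
                X_all = np.hstack(rs_set.X)
                dim = participation_ratio(X_all)
                X_tc = np.hstack(rs_set.X_train)
                gamma = _default_gamma(X_tc)
                Ks = [response_kernel(X, X_tc, gamma) for X in rs_set.X_train]
                _, q = kernel_variance(Ks)
                T2 = Ks[0].shape[0] ** 2
                for target in targets:
                    y = make_target(target, t_grid)
                    model = fit_readout(rs_set.X_train, y, gamma)
                    mse = test_mse(model, rs_set.X_test, y)
                    rows.append({
                        "input_pa": float(I), "delta_v": float(delta),
                        "seed": int(seed), "target": target, "mse": mse,
                        "dimensionality": dim, "kernel_q": q,
                        "kernel_q_norm": q / T2,
                        "oscillation_period": rs_set.oscillation_period,
                    })
    return pd.DataFrame(rows)
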