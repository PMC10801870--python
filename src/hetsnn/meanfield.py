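"""Exact mean-field (Lorentzian-ansatz) rate equations.

Under a Lorentzian distribution of spike thresholds with center
``vtheta_bar`` and HWHM ``delta_v``, the macroscopic dynamics of an
all-to-all Izhikevich network with a global recovery variable reduce to
four ODEs per population in (r, v, u, s), where r is the population
rate in spikes/ms, v the mean membrane potential, u the recovery
variable and s the synaptic activation:

    C dr/dt = delta_v k^2 |v - vr| / (pi C) + r [k(2v - vr - vtheta_bar) - g s]
    C dv/dt = k v (v - vr - vtheta_bar) - pi C r (delta_v sigma_v + pi C r / k)
              + k vr vtheta_bar - u + I + g s (E - v)
    tau_u du/dt = b (v - vr) - u + tau_u kappa r
    tau_s ds/dt = -s + tau_s J r

with sigma_v = sign(v - vr). The heterogeneity terms are written in the
unique dimensionally consistent form (both carry delta_v * k^2 / (pi C)
and pi C r delta_v respectively). Additional conductance-based synapse
types contribute g_m s_m (E_m - v) to dv/dt and -g_m s_m r to C dr/dt,
each s_m low-pass filtering its presynaptic rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .params import NeuronTypeParams

__all__ = [
    "MeanFieldState",
    "Synapse",
    "PopulationGraph",
    "single_population_graph",
    "two_population_graph",
    "mf_derivative",
    "integrate_mf",
    "find_fixed_point",
    "FixedPointResult",
]


@dataclass
class MeanFieldState:
    """Mean-field state of one population: (r, v, u, s).

    r in spikes/ms, v in mV, u in pA, s dimensionless.
    """

    r: float = 0.0
    v: float = -60.0
    u: float = 0.0
    s: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.v, self.u, self.s], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "MeanFieldState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class Synapse:
    """Conductance-based synapse type between populations.

    ``J`` is the dimensionless coupling driving the low-pass filter
    tau_s ds/dt = -s + tau_s J r_pre; the postsynaptic current is
    g s (E - v_post).
    """

    pre: int
    post: int
    J: float
    g: float
    E: float
    tau_s: float


@dataclass
class PopulationGraph:
    """One or more mean-field populations coupled by synapse types."""

    populations: list[tuple[NeuronTypeParams, float]]  # (params, delta_v)
    synapses: list[Synapse] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.populations)
        for syn in self.synapses:
            if not (0 <= syn.pre < n and 0 <= syn.post < n):
                raise ValueError("synapse references unknown population")


def single_population_graph(params: NeuronTypeParams,
                            delta_v: float | None = None) -> PopulationGraph:
    """A lone population with its recurrent synapse."""
    dv = params.delta_v if delta_v is None else delta_v
    return PopulationGraph(
        populations=[(params, dv)],
        synapses=[Synapse(0, 0, params.J, params.g, params.E, params.tau_s)],
    )


def two_population_graph(
    pop_a: NeuronTypeParams, delta_a: float,
    pop_b: NeuronTypeParams, delta_b: float,
    J_aa: float, J_ab: float, J_ba: float, J_bb: float,
) -> PopulationGraph:
    """Two populations with all four synapse types.

    ``J_ab`` couples population b onto population a (post, pre order).
    Conductance and reversal potential of each synapse type follow the
    presynaptic cell type (the transmitter is a property of the source),
    while the filtering time constant follows the presynaptic type's
    tau_s.
    """
    syns = []
    for (post, pre, J) in ((0, 0, J_aa), (0, 1, J_ab), (1, 0, J_ba), (1, 1, J_bb)):
        src = (pop_a, pop_b)[pre]
        syns.append(Synapse(pre, post, J, src.g, src.E, src.tau_s))
    return PopulationGraph(
        populations=[(pop_a, delta_a), (pop_b, delta_b)], synapses=syns)


def mf_derivative(
    state: MeanFieldState,
    params: NeuronTypeParams,
    delta_v: float,
    I: float,
    extra_currents: list[tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Time derivative (dr, dv, du, ds) of a single population.

    ``extra_currents`` is an optional list of (g, s, E) conductance
    inputs from other populations; each contributes g*s*(E - v) to the
    membrane equation and -g*s*r to the rate equation.
    """
    r, v, u, s = state.r, state.v, state.u, state.s
    p = params
    dvr = v - p.vr
    sigma = np.sign(dvr)
    gs = p.g * s
    gsE = p.g * s * (p.E - v)
    if extra_currents:
        for (g_m, s_m, E_m) in extra_currents:
            gs += g_m * s_m
            gsE += g_m * s_m * (E_m - v)
    dr = (delta_v * p.k ** 2 * sigma * dvr / (np.pi * p.C)
          + r * (p.k * (2 * v - p.vr - p.vtheta_bar) - gs)) / p.C
    dv = (p.k * v * (v - p.vr - p.vtheta_bar)
          - np.pi * p.C * r * (delta_v * sigma + np.pi * p.C * r / p.k)
          + p.k * p.vr * p.vtheta_bar - u + I + gsE) / p.C
    du = (p.b * dvr - u) / p.tau_u + p.kappa * r
    ds = (-s + p.tau_s * p.J * r) / p.tau_s
    return np.array([dr, dv, du, ds])


class MeanFieldBlowupError(RuntimeError):
    pass


def _graph_arrays(graph: PopulationGraph):
    pops = graph.populations
    C = np.array([p.C for p, _ in pops])
    k = np.array([p.k for p, _ in pops])
    vr = np.array([p.vr for p, _ in pops])
    vth = np.array([p.vtheta_bar for p, _ in pops])
    tau_u = np.array([p.tau_u for p, _ in pops])
    b = np.array([p.b for p, _ in pops])
    kappa = np.array([p.kappa for p, _ in pops])
    delta = np.array([d for _, d in pops])
    syn_pre = np.array([s.pre for s in graph.synapses], dtype=np.int32)
    syn_post = np.array([s.post for s in graph.synapses], dtype=np.int32)
    syn_J = np.array([s.J for s in graph.synapses])
    syn_g = np.array([s.g for s in graph.synapses])
    syn_E = np.array([s.E for s in graph.synapses])
    syn_tau = np.array([s.tau_s for s in graph.synapses])
    return C, k, vr, vth, tau_u, b, kappa, delta, syn_pre, syn_post, syn_J, syn_g, syn_E, syn_tau


def integrate_mf(
    graph: PopulationGraph,
    I: np.ndarray | list | float,
    duration: float,
    dt: float = 0.01,
    init: list[MeanFieldState] | None = None,
    init_s: np.ndarray | None = None,
    record_dt: float = 0.1,
) -> pd.DataFrame:
    """Explicit-Euler trajectory of all populations in a graph.

    Parameters
    ----------
    I
        Input current per population: a scalar (same constant for all),
        a 1-D array of per-population constants, or a 2-D array of shape
        (n_pop, n_steps) sampled on the integration grid.
    init, init_s
        Initial population states and per-synapse activations. By
        default populations start quiescent at v = vr with the
        recurrent synapses at their init-state-consistent value 0.

    Returns a tidy frame (time_ms, population, r, v, u, s) where s is
    the summed activation of the population's afferent synapses; the
    per-synapse trace is attached as ``frame.attrs["s_syn"]``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    arrays = _graph_arrays(graph)
    C = arrays[0]
    n_pop = len(C)
    n_syn = len(graph.synapses)
    n_steps = int(round(duration / dt))

    I_arr = np.asarray(I, dtype=float)
    if I_arr.ndim == 0:
        I_t = np.full((n_pop, n_steps), float(I_arr))
    elif I_arr.ndim == 1:
        I_t = np.repeat(I_arr[:, None], n_steps, axis=1)
    else:
        if I_arr.shape != (n_pop, n_steps):
            raise ValueError(f"expected I of shape ({n_pop}, {n_steps})")
        I_t = np.ascontiguousarray(I_arr)

    if init is None:
        init = [MeanFieldState(r=0.0, v=p.vr, u=0.0, s=0.0)
                for p, _ in graph.populations]
    r = np.array([st.r for st in init], dtype=float)
    v = np.array([st.v for st in init], dtype=float)
    u = np.array([st.u for st in init], dtype=float)
    if init_s is None:
        # a population's own s field seeds its recurrent synapse; cross
        # synapses start at the value consistent with the presynaptic rate
        s = np.zeros(n_syn)
        for m, syn in enumerate(graph.synapses):
            s[m] = (init[syn.pre].s if syn.pre == syn.post
                    else syn.tau_s * syn.J * r[syn.pre])
    else:
        s = np.asarray(init_s, dtype=float).copy()

    rec_every = max(int(round(record_dt / dt)), 1)
    n_rec = n_steps // rec_every + 1
    rec = np.zeros((n_rec, n_pop, 3))
    rec_s = np.zeros((n_rec, max(n_syn, 1)))
    if n_syn == 0:
        # kernel requires at least dummy synapse arrays
        syn_arrays = (np.zeros(0, dtype=np.int32), np.zeros(0, dtype=np.int32),
                      np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0))
        s_run = np.zeros(0)
        rec_s = np.zeros((n_rec, 0))
    else:
        syn_arrays = arrays[8:]
        s_run = s

    status, stop = _kernels.mf_euler(
        r, v, u, s_run, *arrays[:8], *syn_arrays,
        I_t, dt, n_steps, rec_every, rec, rec_s)
    if status == _kernels.ERR_NONFINITE:
        raise MeanFieldBlowupError(
            f"mean-field state became non-finite at step {stop} "
            f"(t = {stop * dt:.3f} ms)")

    # the kernel records at the top of each step; close the trace with
    # the final state
    rec[-1, :, 0] = r
    rec[-1, :, 1] = v
    rec[-1, :, 2] = u
    rec_s[-1, :] = s_run
    t = np.arange(n_rec) * rec_every * dt
    t[-1] = duration
    frames = []
    for p in range(n_pop):
        s_post = np.zeros(n_rec)
        for m, syn in enumerate(graph.synapses):
            if syn.post == p:
                s_post += rec_s[:, m]
        frames.append(pd.DataFrame({
            "time_ms": t, "population": p,
            "r": rec[:, p, 0], "v": rec[:, p, 1], "u": rec[:, p, 2],
            "s": s_post,
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["s_syn"] = rec_s
    out.attrs["final_state"] = [
        MeanFieldState(r=float(r[p]), v=float(v[p]), u=float(u[p]),
                       s=float(sum(s_run[m] for m, syn in enumerate(graph.synapses)
                                   if syn.post == p)))
        for p in range(n_pop)]
    out.attrs["final_s_syn"] = s_run.copy()
    return out


@dataclass
class FixedPointResult:
    state: MeanFieldState
    eigenvalues: np.ndarray
    stable: bool
    residual: float


class FixedPointError(RuntimeError):
    pass


# scaling used to make the Newton residual norm dimensionless-ish:
# r ~ 0.01 spikes/ms, v ~ 10 mV, u ~ 10 pA, s ~ 1
_SCALE = np.array([0.01, 10.0, 10.0, 1.0])


def find_fixed_point(
    params: NeuronTypeParams,
    delta_v: float,
    I: float,
    guess: MeanFieldState,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> FixedPointResult:
    """Damped-Newton search for a stationary state of one population.

    Returns the state, the Jacobian eigenvalues at the root, and a
    stability flag (all eigenvalue real parts negative). Raises
    :class:`FixedPointError` on non-convergence.
    """

    def f(y: np.ndarray) -> np.ndarray:
        return mf_derivative(MeanFieldState.from_array(y), params, delta_v, I)

    def jac(y: np.ndarray) -> np.ndarray:
        J = np.empty((4, 4))
        h0 = 1e-7
        for j in range(4):
            h = h0 * max(1.0, abs(y[j]))
            yp = y.copy(); yp[j] += h
            ym = y.copy(); ym[j] -= h
            J[:, j] = (f(yp) - f(ym)) / (2 * h)
        return J

    y = guess.as_array()
    for _ in range(max_iter):
        fy = f(y)
        res = float(np.linalg.norm(fy / _SCALE))
        if res < tol:
            ev = np.linalg.eigvals(jac(y))
            return FixedPointResult(
                state=MeanFieldState.from_array(y), eigenvalues=ev,
                stable=bool(np.all(ev.real < 0)), residual=res)
        try:
            step = np.linalg.solve(jac(y), -fy)
        except np.linalg.LinAlgError as exc:
            raise FixedPointError(f"singular Jacobian at {y}") from exc
        # backtracking line search on the scaled residual norm
        lam = 1.0
        accepted = False
        while lam > 1e-8:
            y_new = y + lam * step
            if np.all(np.isfinite(y_new)):
                f_new = f(y_new)
                if np.all(np.isfinite(f_new)) and \
                        np.linalg.norm(f_new / _SCALE) < res:
                    accepted = True
                    break
            lam /= 2
        if not accepted:
            raise FixedPointError(
                f"Newton line search stalled at residual {res:.2e}; "
                "the guess may lie outside any basin of attraction")
        y = y_new
        if not np.all(np.isfinite(y)):
            raise FixedPointError("Newton iteration diverged to non-finite state")
    raise FixedPointError(
        f"no convergence after {max_iter} iterations (residual {res:.2e}); "
        "try a guess closer to an attractor")
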