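"""Cell-type parameter presets and quenched spike-threshold disorder.

Each neural population is characterized by the electrophysiological
constants of one Izhikevich cell type (regular-spiking, fast-spiking,
low-threshold-spiking) plus a disorder specification for the quenched
spike thresholds: a truncated Lorentzian (Cauchy) or Gaussian
distribution centered on the nominal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
from scipy import stats

__all__ = [
    "NeuronTypeParams",
    "DisorderSpec",
    "preset",
    "default_truncation",
    "sample_thresholds",
    "truncated_cdf",
    "gaussian_equivalent_width",
]

# Standard-normal quantile at p=0.75; Gaussian IQR = 2 * _Z75 * sd.
_Z75 = float(stats.norm.ppf(0.75))


@dataclass(frozen=True)
class NeuronTypeParams:
    """Electrophysiological constants of one cell type.

    Units: C in pF, k in nS/mV, potentials in mV, conductances in nS,
    time constants in ms, kappa (spike-frequency adaptation) in pA,
    J (recurrent coupling) dimensionless, delta_v (default threshold
    heterogeneity, Lorentzian HWHM) in mV.
    """

    name: str
    C: float
    k: float
    vr: float
    vtheta_bar: float
    g: float
    E: float
    tau_u: float
    tau_s: float
    kappa: float
    b: float
    J: float
    delta_v: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.k <= 0:
            raise ValueError("C and k must be positive")
        if self.tau_u <= 0 or self.tau_s <= 0:
            raise ValueError("time constants must be positive")
        if self.delta_v < 0:
            raise ValueError("delta_v must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


_PRESETS: dict[str, NeuronTypeParams] = {
    # Regular-spiking (excitatory) cortical neuron.
    "rs": NeuronTypeParams(
        name="rs", C=100.0, k=0.7, vr=-60.0, vtheta_bar=-40.0,
        g=1.0, E=0.0, tau_u=33.33, tau_s=6.0, kappa=10.0, b=-2.0,
        J=15.0, delta_v=0.5,
    ),
    # Fast-spiking (inhibitory) interneuron.
    "fs": NeuronTypeParams(
        name="fs", C=20.0, k=1.0, vr=-55.0, vtheta_bar=-40.0,
        g=1.0, E=-65.0, tau_u=5.0, tau_s=8.0, kappa=0.0, b=0.025,
        J=5.0, delta_v=1.0,
    ),
    # Low-threshold-spiking (inhibitory) interneuron.
    "lts": NeuronTypeParams(
        name="lts", C=100.0, k=1.0, vr=-56.0, vtheta_bar=-42.0,
        g=1.0, E=-65.0, tau_u=33.33, tau_s=8.0, kappa=20.0, b=8.0,
        J=5.0, delta_v=1.0,
    ),
}


def preset(cell_type: str, kappa_override: float | None = None) -> NeuronTypeParams:
    """Return the shipped parameter set for ``cell_type``.

    Parameters
    ----------
    cell_type
        One of ``"rs"``, ``"fs"``, ``"lts"``.
    kappa_override
        Replacement value for the spike-frequency-adaptation strength
        kappa (pA), e.g. 100 pA for a strongly adapting regular-spiking
        population.
    """
    try:
        p = _PRESETS[cell_type.lower()]
    except KeyError:
        raise ValueError(
            f"unknown cell type {cell_type!r}; expected one of {sorted(_PRESETS)}"
        ) from None
    if kappa_override is not None:
        p = replace(p, kappa=float(kappa_override))
    return p


def default_truncation(params: NeuronTypeParams, epsilon_margin: float = 0.0) -> tuple[float, float]:
    """Default truncation bounds for the spike-threshold distribution.

    The lower bound keeps every threshold above the resting potential
    (plus an optional margin); the upper bound mirrors it about the
    distribution center so the truncated distribution stays symmetric.
    """
    if params.vtheta_bar <= params.vr:
        raise ValueError("vtheta_bar must exceed vr to define a truncation window")
    low = params.vr + epsilon_margin
    high = 2.0 * params.vtheta_bar - low
    if low >= high:
        raise ValueError("epsilon_margin too large: empty truncation window")
    return low, high


@dataclass(frozen=True)
class DisorderSpec:
    """Quenched spike-threshold disorder.

    ``width`` is the half-width-at-half-maximum for ``family="lorentzian"``
    and the standard deviation for ``family="gaussian"``. Truncation is
    symmetric about ``center`` and samples fall strictly inside the open
    interval (truncation_low, truncation_high).
    """

    family: str
    center: float
    width: float
    truncation_low: float
    truncation_high: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown disorder family {self.family!r}")
        if self.width < 0:
            raise ValueError("width must be non-negative")
        if not (self.truncation_low < self.center < self.truncation_high):
            raise ValueError("truncation bounds must bracket the center")
        if not np.isclose(
            self.truncation_high - self.center, self.center - self.truncation_low
        ):
            raise ValueError("truncation must be symmetric about the center")

    def to_dict(self) -> dict:
        return asdict(self)


def _frozen_dist(spec: DisorderSpec):
    if spec.family == "lorentzian":
        return stats.cauchy(loc=spec.center, scale=spec.width)
    return stats.norm(loc=spec.center, scale=spec.width)


def truncated_cdf(spec: DisorderSpec, x: np.ndarray) -> np.ndarray:
    """Analytic CDF of the truncated disorder distribution."""
    if spec.width == 0:
        return (np.asarray(x, dtype=float) >= spec.center).astype(float)
    dist = _frozen_dist(spec)
    f_lo = dist.cdf(spec.truncation_low)
    f_hi = dist.cdf(spec.truncation_high)
    c = np.clip((dist.cdf(x) - f_lo) / (f_hi - f_lo), 0.0, 1.0)
    return c


def sample_thresholds(spec: DisorderSpec, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` i.i.d. quenched spike thresholds (mV).

    Sampling uses the inverse CDF restricted to the quantile interval of
    the truncation bounds, so the draw is exact and deterministic given
    the seed; values are strictly inside the open truncation interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.width == 0:
        return np.full(n, spec.center, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dist = _frozen_dist(spec)
    f_lo = dist.cdf(spec.truncation_low)
    f_hi = dist.cdf(spec.truncation_high)
    # open-interval uniforms: reject the (measure-zero) endpoints
    u = rng.uniform(f_lo, f_hi, size=n)
    while True:
        on_edge = (u <= f_lo) | (u >= f_hi)
        if not on_edge.any():
            break
        u[on_edge] = rng.uniform(f_lo, f_hi, size=int(on_edge.sum()))
    x = dist.ppf(u)
    return np.clip(x, np.nextafter(spec.truncation_low, spec.truncation_high),
                   np.nextafter(spec.truncation_high, spec.truncation_low))


def gaussian_equivalent_width(delta: float) -> float:
    """Gaussian SD whose interquartile range matches a Lorentzian HWHM.

    The Lorentzian IQR equals 2*delta; a Gaussian has IQR
    2*z75*sd with z75 ~ 0.674, hence sd = delta / z75.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    return delta / _Z75
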