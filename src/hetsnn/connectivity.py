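"""Network connectivity: all-to-all, sparse random, and ring topologies.

Every neuron receives exactly ``floor(p*N)`` presynaptic inputs of equal
strength ``J/(p*N)``, which preserves the total recurrent drive J of the
all-to-all mean-field limit. Ring networks draw presynaptic partners
from a power-law kernel of the circular distance, density ~ dist^-d.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import sparse

__all__ = ["ConnectivitySpec", "CouplingMatrix", "build_connectivity",
           "build_cross_connectivity", "ring_partner_probs"]

TOPOLOGIES = ("all_to_all", "random_sparse", "ring_power_law")


@dataclass(frozen=True)
class ConnectivitySpec:
    n_neurons: int
    topology: str = "random_sparse"
    coupling_prob: float = 0.2
    ring_exponent: float = 0.0
    allow_self: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (0 < self.coupling_prob <= 1):
            raise ValueError("coupling_prob must be in (0, 1]")
        if self.topology == "all_to_all" and self.coupling_prob != 1.0:
            raise ValueError("all_to_all implies coupling_prob == 1")
        if self.ring_exponent < 0:
            raise ValueError("ring_exponent must be >= 0")
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CouplingMatrix:
    """Row-oriented coupling: weights[i, j] is the strength j -> i."""

    weights: sparse.csr_matrix
    in_degree: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]


def ring_partner_probs(n: int, target: int, d: float, allow_self: bool = False) -> np.ndarray:
    """Sampling probabilities of each presynaptic partner on the ring.

    Circular distance dist(x, y) = min(|x-y|, N-|x-y|); probability of
    partner y for target x is proportional to dist^-d, self excluded
    unless ``allow_self`` (a self-distance of 0 is undefined under the
    power law, so self connections get probability 0 regardless of d>0).
    """
    idx = np.arange(n)
    dist = np.abs(idx - target)
    dist = np.minimum(dist, n - dist).astype(float)
    with np.errstate(divide="ignore"):
        w = np.where(dist > 0, dist ** (-d), 0.0)
    if allow_self and d == 0:
        w[target] = 1.0
    total = w.sum()
    if total == 0:
        raise ValueError("no admissible partners")
    return w / total


def build_connectivity(spec: ConnectivitySpec, J: float) -> CouplingMatrix:
    """Sample a coupling matrix with ``floor(p*N)`` inputs per neuron.

    Presynaptic partners are drawn without replacement; each nonzero
    weight equals ``J / (p*N)``. Deterministic given ``spec.seed``.
    """
    n = spec.n_neurons
    p = spec.coupling_prob
    k_in = int(np.floor(p * n))
    if k_in < 1:
        raise ValueError("coupling_prob * n_neurons must be >= 1")
    max_partners = n if spec.allow_self else n - 1
    if k_in > max_partners:
        k_in = max_partners
    w = J / (p * n)
    rng = np.random.default_rng(spec.seed)

    rows = np.repeat(np.arange(n), k_in)
    cols = np.empty(n * k_in, dtype=np.int64)
    if spec.topology == "all_to_all":
        for i in range(n):
            cand = np.arange(n) if spec.allow_self else np.delete(np.arange(n), i)
            cols[i * k_in:(i + 1) * k_in] = cand[:k_in]
    elif spec.topology == "random_sparse":
        for i in range(n):
            cand = np.arange(n) if spec.allow_self else np.concatenate(
                (np.arange(i), np.arange(i + 1, n)))
            cols[i * k_in:(i + 1) * k_in] = rng.choice(cand, size=k_in, replace=False)
    else:  # ring_power_law
        # Draw pN partners per neuron i.i.d. from the power-law kernel and
        # sum duplicate draws. Sampling without replacement would force
        # most partners out of the (narrow) kernel bulk once p*N exceeds
        # the local neighborhood, destroying the spatial locality the
        # ring kernel exists to provide; repeated draws instead keep the
        # synaptic mass profile proportional to dist^-d with total row
        # weight J.
        for i in range(n):
            probs = ring_partner_probs(n, i, spec.ring_exponent, spec.allow_self)
            cols[i * k_in:(i + 1) * k_in] = rng.choice(n, size=k_in, replace=True, p=probs)

    weights = sparse.csr_matrix(
        (np.full(n * k_in, w), (rows, cols)), shape=(n, n))
    weights.sum_duplicates()
    in_degree = np.diff(weights.indptr)
    return CouplingMatrix(weights=weights, in_degree=in_degree)


def build_cross_connectivity(n_post: int, n_pre: int, coupling_prob: float,
                             J: float, seed: int = 0) -> CouplingMatrix:
    """Random sparse coupling between two distinct populations.

    Each postsynaptic neuron receives ``floor(p * n_pre)`` inputs of
    strength ``J / (p * n_pre)`` from distinct presynaptic partners.
    """
    if not (0 < coupling_prob <= 1):
        raise ValueError("coupling_prob must be in (0, 1]")
    k_in = int(np.floor(coupling_prob * n_pre))
    if k_in < 1:
        raise ValueError("coupling_prob * n_pre must be >= 1")
    w = J / (coupling_prob * n_pre)
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(n_post), k_in)
    cols = np.empty(n_post * k_in, dtype=np.int64)
    for i in range(n_post):
        cols[i * k_in:(i + 1) * k_in] = rng.choice(n_pre, size=k_in, replace=False)
    weights = sparse.csr_matrix(
        (np.full(n_post * k_in, w), (rows, cols)), shape=(n_post, n_pre))
    return CouplingMatrix(weights=weights, in_degree=np.diff(weights.indptr))
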