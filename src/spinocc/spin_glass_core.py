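"""Pairwise maximum-entropy (spin-glass) model: Hamiltonian and exact enumeration.

The model over spin states S = (s_1, ..., s_N), s_i in {-1, +1}, is

    H(S) = - sum_i h_i s_i - sum_{i<j} J_ij s_i s_j
    P(S) = exp(-beta * H(S)) / Z,

the least-structured (maximum-entropy) distribution constrained to match
first moments <s_i> and pairwise moments <s_i s_j>.  h_i is a per-node bias
(attraction to the site), J_ij a symmetric pairwise coupling (collective
coordination between sites), and beta is fixed to 1 by convention.

Everything here works by exact enumeration over the 2^N states, which is
the appropriate tool for small node counts (the enumeration cap defaults to
20 nodes, about a million states); beyond the cap, Monte Carlo estimation in
:mod:`spinocc.mc_dynamics` is the supported route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .occupancy_data import MomentSet, StateDistribution, pair_indices

__all__ = [
    "SpinGlassModel",
    "ENUMERATION_CAP",
    "hamiltonian",
    "enumerate_spin_states",
    "boltzmann_distribution",
    "model_moments",
    "save_model",
    "load_model",
]

ENUMERATION_CAP = 20


@dataclass
class SpinGlassModel:
    """Fields h (per node), symmetric couplings J (per pair), inverse temperature beta."""

    h: np.ndarray
    J: np.ndarray
    beta: float = 1.0
    node_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.size
        if self.J.shape != (n, n):
            raise ValueError("J must be an N x N matrix")
        if not np.isfinite(self.h).all() or not np.isfinite(self.J).all():
            raise ValueError("model parameters must be finite")
        if not np.allclose(self.J, self.J.T, atol=0):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have zero diagonal")
        if not self.node_labels:
            self.node_labels = list(range(1, n + 1))

    @property
    def n_nodes(self) -> int:
        return self.h.size

    @property
    def J_upper(self) -> np.ndarray:
        """Upper-triangle couplings as a flat vector in pair_indices order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.J[iu]

    @classmethod
    def from_upper(cls, h: np.ndarray, J_upper: np.ndarray, beta: float = 1.0,
                   node_labels: list | None = None) -> "SpinGlassModel":
        h = np.asarray(h, dtype=float)
        n = h.size
        J = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        J[iu] = np.asarray(J_upper, dtype=float)
        J += J.T
        return cls(h, J, beta, node_labels or [])


def enumerate_spin_states(n_nodes: int) -> np.ndarray:
    """All 2^N spin states as a (2^N, N) array of +/-1, code c -> row c.

    Bit convention matches :func:`spinocc.occupancy_data.encode_states`:
    node 1 (column 0) is the least-significant bit of the state code.
    """
    if n_nodes > ENUMERATION_CAP:
        raise ValueError(
            f"N={n_nodes} exceeds the enumeration cap ({ENUMERATION_CAP}); "
            "use Monte Carlo estimation instead"
        )
    codes = np.arange(2**n_nodes, dtype=np.int64)
    occ = (codes[:, None] >> np.arange(n_nodes)) & 1
    return (2 * occ - 1).astype(np.float64)


def hamiltonian(model: SpinGlassModel, states: np.ndarray | int) -> np.ndarray | float:
    """Energy H(S) for one state code or an array of codes."""
    scalar = np.isscalar(states)
    codes = np.atleast_1d(np.asarray(states, dtype=np.int64))
    n = model.n_nodes
    if codes.size and (codes.min() < 0 or codes.max() >= 2**n):
        raise ValueError("state code out of range for model dimension")
    occ = (codes[:, None] >> np.arange(n)) & 1
    spins = (2 * occ - 1).astype(float)
    pairs = pair_indices(n)
    i = np.array([p[0] for p in pairs], dtype=int)
    j = np.array([p[1] for p in pairs], dtype=int)
    energy = -(spins @ model.h) - (spins[:, i] * spins[:, j]) @ model.J_upper
    return float(energy[0]) if scalar else energy


def _log_weights(model: SpinGlassModel) -> np.ndarray:
    spins = enumerate_spin_states(model.n_nodes)
    pairs = pair_indices(model.n_nodes)
    i = np.array([p[0] for p in pairs], dtype=int)
    j = np.array([p[1] for p in pairs], dtype=int)
    energy = -(spins @ model.h) - (spins[:, i] * spins[:, j]) @ model.J_upper
    return -model.beta * energy


def boltzmann_distribution(model: SpinGlassModel) -> StateDistribution:
    """Exact Boltzmann distribution over all 2^N states (log-sum-exp stabilised)."""
    logw = _log_weights(model)
    probs = np.exp(logw - logsumexp(logw))
    probs /= probs.sum()
    return StateDistribution(probs, model.n_nodes, origin="model")


def log_partition(model: SpinGlassModel) -> float:
    """log Z by exact enumeration."""
    return float(logsumexp(_log_weights(model)))


def model_moments(model: SpinGlassModel) -> MomentSet:
    """Exact <s_i> and <s_i s_j> (and their occupancy-basis images) under P(S)."""
    dist = boltzmann_distribution(model)
    spins = enumerate_spin_states(model.n_nodes)
    pairs = pair_indices(model.n_nodes)
    i = np.array([p[0] for p in pairs], dtype=int)
    j = np.array([p[1] for p in pairs], dtype=int)
    spin_means = dist.probs @ spins
    spin_pairs = dist.probs @ (spins[:, i] * spins[:, j])
    return MomentSet.from_spin(spin_means, spin_pairs)


def save_model(model: SpinGlassModel, path: str | Path) -> Path:
    """Serialize to JSON (full decimal precision; round-trips exactly)."""
    path = Path(path)
    pairs = pair_indices(model.n_nodes)
    payload = {
        "format": "spinocc-model-v1",
        "node_labels": [str(x) for x in model.node_labels],
        "beta": model.beta,
        "h": [float(x).hex() for x in model.h],
        "J_upper": {
            f"{a + 1},{b + 1}": float(v).hex()
            for (a, b), v in zip(pairs, model.J_upper)
        },
    }
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def load_model(path: str | Path) -> SpinGlassModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "spinocc-model-v1":
        raise ValueError(f"unrecognised model file format in {path}")
    h = np.array([float.fromhex(x) for x in payload["h"]])
    n = h.size
    J_upper = np.zeros(n * (n - 1) // 2)
    order = {pair: k for k, pair in enumerate(pair_indices(n))}
    for key, val in payload["J_upper"].items():
        a, b = (int(t) - 1 for t in key.split(","))
        J_upper[order[(a, b)]] = float.fromhex(val)
    return SpinGlassModel.from_upper(
        h, J_upper, beta=payload.get("beta", 1.0),
        node_labels=payload.get("node_labels") or None,
    )
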