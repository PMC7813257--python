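"""Metropolis Monte Carlo dynamics for the pairwise occupancy model.

A "simulation step" is one sweep: N single-site update attempts at randomly
chosen sites.  Each attempt proposes flipping the chosen spin and accepts
with the Metropolis probability min(1, exp(-beta * dH)) (a Glauber heat-bath
kernel is available as an option); both kernels satisfy detailed balance
with respect to the model's Boltzmann distribution and differ only in
relaxation speed, which the time-scale calibration absorbs.

Trials mirror the experimental protocol: every trial starts from the
all-empty state I = 0 and the occupancy after each sweep is recorded, giving
an ensemble of binary steps x nodes trajectories.  Mapping sweeps to real
time is done afterwards by grid-searching a seconds-per-step factor against
a reference mean-occupancy curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .occupancy_data import StateDistribution, decode_state, encode_states
from .spin_glass_core import SpinGlassModel

__all__ = [
    "TrajectoryEnsemble",
    "TimeScaleCalibration",
    "metropolis_step",
    "run_chain_occupancy",
    "simulate_trials",
    "chain_state_distribution",
    "calibrate_timescale",
]

_KERNELS = {"metropolis": _kernels.METROPOLIS, "glauber": _kernels.GLAUBER}

# pre-drawn randomness is chunked to bound memory on long chains
_CHUNK_SWEEPS = 200_000


@dataclass
class TrajectoryEnsemble:
    """Simulated trials: binary occupancy, shape (n_trials, steps, nodes)."""

    trials: np.ndarray
    seconds_per_step: float = 1.0
    seed: int | None = None
    model_ref: str = ""

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials)
        if self.trials.ndim != 3:
            raise ValueError("trials must have shape (n_trials, steps, nodes)")
        if self.trials.size and not np.isin(self.trials, (0, 1)).all():
            raise ValueError("trajectory entries must be binary")
        self.trials = self.trials.astype(np.uint8)
        if self.seconds_per_step <= 0:
            raise ValueError("seconds_per_step must be positive")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_steps(self) -> int:
        return self.trials.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.trials.shape[2]

    def mean_occupancy_per_step(self) -> np.ndarray:
        """Node- and trial-averaged occupancy after each sweep."""
        return self.trials.mean(axis=(0, 2))


@dataclass
class TimeScaleCalibration:
    """Grid search result for the seconds-per-sweep factor."""

    grid: np.ndarray
    objective: np.ndarray
    best: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if self.best not in self.grid:
            raise ValueError("best scale must be a grid candidate")
        if not np.isfinite(self.objective).all():
            raise ValueError("objective must be finite on the grid")


def _run_occ(model: SpinGlassModel, s0: np.ndarray, n_sweeps: int,
             rng: np.random.Generator, kernel: str) -> tuple[np.ndarray, np.ndarray]:
    """Run a chain, returning (occupancy per sweep, final spin state)."""
    n = model.n_nodes
    kcode = _KERNELS[kernel]
    out = np.empty((n_sweeps, n), dtype=np.int8)
    s = s0.astype(np.int8)
    done = 0
    while done < n_sweeps:
        chunk = min(_CHUNK_SWEEPS, n_sweeps - done)
        sites = rng.integers(0, n, size=chunk * n)
        us = rng.random(chunk * n)
        s = _kernels.run_chain(
            model.h, model.J, model.beta, s, chunk, sites, us, kcode,
            out[done : done + chunk],
        )
        done += chunk
    return out.astype(np.uint8), s


def metropolis_step(model: SpinGlassModel, state: int,
                    rng: np.random.Generator, kernel: str = "metropolis") -> int:
    """One sweep (N attempted single-site flips) from a state code; returns the new code."""
    occ = decode_state(state, model.n_nodes)[0]
    s0 = (2 * occ.astype(np.int8) - 1)
    out, _ = _run_occ(model, s0, 1, rng, kernel)
    return int(encode_states(out[0])[0])


def run_chain_occupancy(model: SpinGlassModel, n_sweeps: int,
                        rng: np.random.Generator, initial_code: int = 0,
                        kernel: str = "metropolis") -> np.ndarray:
    """Occupancy after each of ``n_sweeps`` sweeps, starting from ``initial_code``."""
    occ = decode_state(initial_code, model.n_nodes)[0]
    s0 = 2 * occ.astype(np.int8) - 1
    out, _ = _run_occ(model, s0, n_sweeps, rng, kernel)
    return out


def simulate_trials(model: SpinGlassModel, n_trials: int, steps: int,
                    seed: int = 0, kernel: str = "metropolis",
                    seconds_per_step: float = 1.0) -> TrajectoryEnsemble:
    """Simulate ``n_trials`` independent trials of ``steps`` sweeps each.

    Every trial starts from the all-empty state I = 0, matching the
    experimental initial condition; per-trial RNG streams are spawned
    deterministically from ``seed``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    trials = np.empty((n_trials, steps, model.n_nodes), dtype=np.uint8)
    s0 = -np.ones(model.n_nodes, dtype=np.int8)
    for t, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        trials[t], _ = _run_occ(model, s0, steps, rng, kernel)
    return TrajectoryEnsemble(trials, seconds_per_step, seed,
                              model_ref=f"n_nodes={model.n_nodes}")


def chain_state_distribution(model: SpinGlassModel, n_sweeps: int, seed: int = 0,
                             burn_in: int = 0, kernel: str = "metropolis") -> StateDistribution:
    """Empirical state distribution of one long chain (after burn-in sweeps)."""
    rng = np.random.default_rng(seed)
    occ = run_chain_occupancy(model, burn_in + n_sweeps, rng, kernel=kernel)
    codes = encode_states(occ[burn_in:])
    counts = np.bincount(codes, minlength=2**model.n_nodes).astype(float)
    return StateDistribution(counts / counts.sum(), model.n_nodes, origin="simulated")


def _chain_moments_persistent(h, j_upper, chains, sweeps, rng):
    """Moment estimates from persistent chains (one gradient step of MC-mode fitting)."""
    from .occupancy_data import MomentSet

    n = h.shape[0]
    J = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    J[iu] = j_upper
    J += J.T
    model = SpinGlassModel(h, J)
    new_chains = np.empty_like(chains)
    occ_last = np.empty((chains.shape[0], n), dtype=float)
    for c in range(chains.shape[0]):
        out, s = _run_occ(model, chains[c], sweeps, rng, "metropolis")
        new_chains[c] = s
        occ_last[c] = out[-1]
    ms = MomentSet.from_occupancy_frames(occ_last)
    return ms.spin_means, ms.spin_pairs, new_chains


def step_curve_to_seconds(step_curve: np.ndarray, scale: float,
                          n_seconds: int, initial: float = 0.0) -> np.ndarray:
    """Map a per-sweep curve to a 1 Hz curve by piecewise-constant interpolation.

    Sweep k (1-based) covers real time [k*scale, (k+1)*scale); times before
    the first recorded sweep take ``initial`` (the all-empty start).
    """
    t = np.arange(n_seconds, dtype=float)
    idx = np.minimum((t // scale).astype(int), len(step_curve))
    full = np.concatenate([[initial], np.asarray(step_curve, dtype=float)])
    return full[idx]


def calibrate_timescale(ensemble: TrajectoryEnsemble, reference_curve: np.ndarray,
                        grid: np.ndarray | None = None) -> TimeScaleCalibration:
    """Choose seconds-per-sweep by least squares against a reference <I>(t) curve.

    For each candidate scale the ensemble's per-sweep mean occupancy is
    mapped to the reference's 1 s sampling (piecewise constant) and scored by
    the sum of squared differences over the whole trial; ties go to the
    smaller scale.  Default grid: 5 to 300 s in 5 s increments.
    """
    if grid is None:
        grid = np.arange(5.0, 301.0, 5.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty calibration grid")
    if (grid <= 0).any():
        raise ValueError("grid candidates must be positive")
    reference_curve = np.asarray(reference_curve, dtype=float)
    curve = ensemble.mean_occupancy_per_step()
    objective = np.empty(grid.size)
    for k, scale in enumerate(grid):
        sim = step_curve_to_seconds(curve, scale, reference_curve.size)
        objective[k] = float(np.sum((sim - reference_curve) ** 2))
    order = np.lexsort((grid, objective))  # min objective, then smaller scale
    best = float(grid[order[0]])
    return TimeScaleCalibration(grid, objective, best)
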