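"""Comparison statistics for observed and simulated occupancy patterns.

Covers the descriptive and inferential statistics used to compare data with
the fitted model and its independent-nodes null: node-averaged occupancy
trajectories with across-trial fluctuation bands, per-node stationary
occupancy, persistence-time distributions P(tau), Pearson correlations
between fitted parameters and their empirical observables (h vs <I_i>,
J vs C_ij), and group contrasts (Welch t-test, one-way ANOVA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .mc_dynamics import TrajectoryEnsemble
from .occupancy_data import MomentSet, OccupancySignal, TrialWindow
from .spin_glass_core import SpinGlassModel

__all__ = [
    "OccupancyTrajectoryStats",
    "PersistenceDistribution",
    "ComparisonResult",
    "trials_array",
    "occupancy_trajectory",
    "persistence_distribution",
    "parameter_observable_correlation",
    "group_contrast",
    "log_binned",
]


@dataclass
class OccupancyTrajectoryStats:
    """Trajectory summaries of an ensemble of trials.

    mean_curve: node- and trial-averaged occupancy <I>(t), one value per step.
    sd_curve: across-trial standard deviation (population convention) of the
      node-averaged occupancy at each step.
    per_node_stationary: per-node mean occupancy <I_i> over the stationary
      window, pooled across trials.
    daily_means: per-trial node- and time-averaged occupancy.
    """

    mean_curve: np.ndarray
    sd_curve: np.ndarray
    per_node_stationary: np.ndarray
    daily_means: np.ndarray
    seconds_per_step: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mean_curve", "per_node_stationary", "daily_means"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sd_curve.size and self.sd_curve.min() < -1e-15:
            raise ValueError("sd_curve must be non-negative")


@dataclass
class PersistenceDistribution:
    """Distribution of node persistence times tau (seconds in one state)."""

    taus: np.ndarray
    probs: np.ndarray
    censoring_policy: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.size and abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("persistence probabilities must sum to 1")

    @property
    def mean_tau(self) -> float:
        return float(self.taus @ self.probs)


@dataclass
class ComparisonResult:
    """A correlation or group-contrast statistic with its p-value."""

    statistic: float
    p_value: float
    kind: str  # pearson | t-test | anova
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "pearson" and not -1 - 1e-12 <= self.statistic <= 1 + 1e-12:
            raise ValueError("Pearson correlation must lie in [-1, 1]")


def trials_array(source: OccupancySignal | TrajectoryEnsemble | np.ndarray,
                 windows: Iterable[TrialWindow] | None = None) -> tuple[np.ndarray, float]:
    """Normalise a signal/ensemble/array into (trials, steps, nodes) + step seconds.

    For an :class:`OccupancySignal`, ``windows`` selects one window per trial
    (all must have equal length).
    """
    if isinstance(source, TrajectoryEnsemble):
        return source.trials, source.seconds_per_step
    if isinstance(source, OccupancySignal):
        if windows is None:
            if source.trial_length is None:
                raise ValueError("signal has no trial structure; pass windows")
            arr = source.values.reshape(source.n_trials, source.trial_length,
                                        source.n_nodes)
            return arr, source.frame_period
        windows = list(windows)
        if not windows:
            raise ValueError("empty window selection")
        lengths = {w.n_frames for w in windows}
        if len(lengths) != 1:
            raise ValueError("windows must have equal length to stack trials")
        arr = np.stack([source.trial_values(w) for w in windows])
        return arr, source.frame_period
    arr = np.asarray(source)
    if arr.ndim != 3:
        raise ValueError("expected a (trials, steps, nodes) array")
    return arr, 1.0


def occupancy_trajectory(source, windows: Iterable[TrialWindow] | None = None,
                         stationary: tuple[float, float] | None = None) -> OccupancyTrajectoryStats:
    """Trajectory statistics of an ensemble of trials.

    ``stationary`` is a (start, end) time range in seconds for the per-node
    stationary averages; by default the full trial is used.
    """
    arr, dt = trials_array(source, windows)
    if arr.shape[0] < 1:
        raise ValueError("need at least one trial")
    node_avg = arr.mean(axis=2)  # trials x steps
    mean_curve = node_avg.mean(axis=0)
    sd_curve = node_avg.std(axis=0)  # population (ddof=0) across trials
    if stationary is None:
        lo, hi = 0, arr.shape[1]
    else:
        lo = int(round(stationary[0] / dt))
        hi = int(round(stationary[1] / dt))
    per_node = arr[:, lo:hi, :].mean(axis=(0, 1))
    daily = arr.mean(axis=(1, 2))
    return OccupancyTrajectoryStats(mean_curve, sd_curve, per_node, daily, dt)


def _run_lengths(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(completed interior run lengths, boundary-touching run lengths)."""
    change = np.flatnonzero(np.diff(series.astype(np.int8)) != 0)
    bounds = np.concatenate([[-1], change, [series.size - 1]])
    runs = np.diff(bounds)
    if runs.size == 1:  # never switches: the single run touches both ends
        return np.empty(0, dtype=int), runs
    return runs[1:-1], runs[[0, -1]]


def persistence_distribution(source, windows: Iterable[TrialWindow] | None = None,
                             censor_boundaries: bool = True) -> PersistenceDistribution:
    """Distribution of times a node stays in one state before switching.

    Run lengths of constant state are collected per node and trial and
    pooled.  Runs touching a window boundary have unknown true length; by
    default they are censored (dropped, but counted in the policy record).
    With ``censor_boundaries=False`` they are kept at their observed length.
    """
    arr, dt = trials_array(source, windows)
    if arr.shape[1] < 2:
        raise ValueError("windows must span at least 2 frames")
    completed: list[np.ndarray] = []
    censored: list[np.ndarray] = []
    for trial in range(arr.shape[0]):
        for node in range(arr.shape[2]):
            runs, edge = _run_lengths(arr[trial, :, node])
            completed.append(runs)
            censored.append(edge)
    comp = np.concatenate(completed)
    cens = np.concatenate(censored)
    policy = {
        "mode": "drop-boundary-runs" if censor_boundaries else "keep-boundary-runs",
        "n_completed": int(comp.size),
        "n_censored": int(cens.size),
        "total_frames": int(comp.sum() + cens.sum()),
    }
    kept = comp if censor_boundaries else np.concatenate([comp, cens])
    if kept.size == 0:
        return PersistenceDistribution(np.empty(0), np.empty(0), policy)
    counts = np.bincount(kept)[1:]  # tau >= 1 frame
    taus = np.arange(1, counts.size + 1) * dt
    mask = counts > 0
    return PersistenceDistribution(taus[mask], counts[mask] / counts.sum(), policy)


def log_binned(dist: PersistenceDistribution, bins_per_decade: int = 8) -> PersistenceDistribution:
    """Re-bin a persistence distribution on a logarithmic tau axis."""
    if dist.taus.size == 0:
        return dist
    lo, hi = np.log10(dist.taus.min()), np.log10(dist.taus.max())
    n_bins = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, hi, n_bins + 1)
    edges[-1] *= 1 + 1e-12
    idx = np.clip(np.searchsorted(edges, dist.taus, side="right") - 1, 0, n_bins - 1)
    probs = np.bincount(idx, weights=dist.probs, minlength=n_bins)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mask = probs > 0
    return PersistenceDistribution(centers[mask], probs[mask] / probs.sum(),
                                   {**dist.censoring_policy, "binning": "log"})


def parameter_observable_correlation(model: SpinGlassModel, moments: MomentSet,
                                     which: str) -> ComparisonResult:
    """Pearson correlation between fitted parameters and empirical observables.

    ``which`` selects ``"h-vs-occupancy"`` (h_i against <I_i>, N points) or
    ``"J-vs-Cij"`` (J_ij against the raw pair moment C_ij = <I_i I_j>,
    N(N-1)/2 points).
    """
    if model.n_nodes != moments.n_nodes:
        raise ValueError("model and moments dimensions differ")
    if which == "h-vs-occupancy":
        x, y = model.h, moments.occ_means
    elif which == "J-vs-Cij":
        x, y = model.J_upper, moments.occ_pairs
    else:
        raise ValueError(f"unknown correlation mode: {which!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return ComparisonResult(float(r), float(p), "pearson",
                            {"n_points": int(np.size(x)), "which": which})


def group_contrast(values: Sequence[float], labels: Sequence[str],
                   kind: str = "t-test") -> ComparisonResult:
    """Contrast a quantity between two labelled groups (e.g. high/low food).

    ``t-test`` runs Welch's two-sample t-test; the reported p-value is
    two-sided (halve it for the one-sided reading).  ``anova`` runs one-way
    ANOVA across however many labels are present.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names, counts = np.unique(labels, return_counts=True)
    groups = [values[labels == g] for g in names]
    if any(c < 1 for c in counts):
        raise ValueError("both groups must be non-empty")
    meta = {str(g): int(c) for g, c in zip(names, counts)}
    if kind == "t-test":
        if len(groups) != 2:
            raise ValueError("t-test needs exactly two groups")
        if all(np.ptp(g) == 0 for g in groups):
            if groups[0][0] == groups[1][0]:  # identical constants: no difference
                return ComparisonResult(0.0, 1.0, "t-test", meta)
            raise ValueError("degenerate within-group variance: t undefined")
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        if not np.isfinite(t):
            raise ValueError("degenerate within-group variance: t undefined")
        return ComparisonResult(float(t), float(p), "t-test", meta)
    if kind == "anova":
        f, p = stats.f_oneway(*groups)
        return ComparisonResult(float(f), float(p), "anova", meta)
    raise ValueError(f"unknown contrast kind: {kind!r}")
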