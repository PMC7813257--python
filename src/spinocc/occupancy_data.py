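"""Binary occupancy signals: ingestion, trial segmentation, state encoding, moments.

The central object is the occupancy signal I(t) = (I_1(t), ..., I_N(t)): a
frames x nodes matrix of 0/1 entries, where I_i(t) = 1 means spatial node i
holds at least one individual at frame t.  Frames are sampled at a fixed
period (1 s by default) and organised into daily trials of equal length.

Joint node states are encoded as integers: node 1 is the least-significant
bit, so code = sum_i I_i * 2^(i-1) and code 0 is the all-empty state.  The
spin basis s_i = 2 I_i - 1 in {-1, +1} is used by the model-fitting layers;
this module keeps both bases consistent through that affine map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancySignal",
    "TrialWindow",
    "StateDistribution",
    "MomentSet",
    "read_occupancy",
    "write_occupancy",
    "segment_trials",
    "stationary_slice",
    "encode_states",
    "decode_state",
    "empirical_distribution",
    "empirical_moments",
    "pair_indices",
]


def pair_indices(n_nodes: int) -> list[tuple[int, int]]:
    """Ordered list of unordered node pairs (i, j) with i < j, row-major."""
    r, c = np.triu_indices(n_nodes, k=1)
    return list(zip(r.tolist(), c.tolist()))


@dataclass
class OccupancySignal:
    """A frames x nodes binary occupancy matrix with trial metadata.

    Parameters
    ----------
    values
        Array of shape (frames, nodes) with entries in {0, 1}.
    frame_period
        Seconds per frame (default 1.0).
    node_labels
        Ordered node identifiers; defaults to 1..N.
    trial_length
        Frames per trial, when the signal is organised in equal trials.
    n_trials
        Number of trials (days).  When both trial fields are set,
        frames must equal trial_length * n_trials.
    """

    values: np.ndarray
    frame_period: float = 1.0
    node_labels: list | None = None
    trial_length: int | None = None
    n_trials: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("occupancy values must be a frames x nodes matrix")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            bad = self.values[~np.isin(self.values, (0, 1))][0]
            raise ValueError(f"non-binary occupancy value: {bad!r}")
        self.values = self.values.astype(np.uint8)
        if self.n_nodes < 1:
            raise ValueError("need at least one node")
        if self.node_labels is None:
            self.node_labels = list(range(1, self.n_nodes + 1))
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length must match node count")
        if len(set(map(str, self.node_labels))) != self.n_nodes:
            raise ValueError("node_labels must be unique")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if self.trial_length is not None and self.n_trials is not None:
            if self.n_frames != self.trial_length * self.n_trials:
                raise ValueError(
                    f"frames ({self.n_frames}) != trial_length ({self.trial_length})"
                    f" x n_trials ({self.n_trials})"
                )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def trial_values(self, window: "TrialWindow") -> np.ndarray:
        """Frames of one trial window, shape (end-start, nodes)."""
        if self.trial_length is None:
            raise ValueError("signal has no trial structure")
        base = window.trial_index * self.trial_length
        return self.values[base + window.start : base + window.end]

    def frames_in(self, windows: Iterable["TrialWindow"]) -> np.ndarray:
        """Concatenated frames of the selected windows (order-preserving)."""
        parts = [self.trial_values(w) for w in windows]
        if not parts:
            raise ValueError("empty window selection")
        return np.concatenate(parts, axis=0)


@dataclass(frozen=True)
class TrialWindow:
    """Half-open frame range [start, end) within one trial (0-based day index)."""

    trial_index: int
    start: int
    end: int
    regime: str = "custom"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid frame range [{self.start}, {self.end})")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class StateDistribution:
    """Probability vector over all 2^N joint occupancy states."""

    probs: np.ndarray
    n_nodes: int
    origin: str = "empirical"  # empirical | model | simulated

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (2**self.n_nodes,):
            raise ValueError("probs length must be 2^N")
        if (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    def occupancy_marginals(self) -> np.ndarray:
        """P(I_i = 1) per node: sum of probs over states with bit i set."""
        codes = np.arange(2**self.n_nodes)
        occ = ((codes[:, None] >> np.arange(self.n_nodes)) & 1).astype(float)
        return occ.T @ self.probs

    def moments(self) -> "MomentSet":
        """Exact first and pairwise moments under this distribution."""
        codes = np.arange(2**self.n_nodes)
        occ = ((codes[:, None] >> np.arange(self.n_nodes)) & 1).astype(float)
        return MomentSet.from_occupancy_frames(occ, weights=self.probs)


@dataclass
class MomentSet:
    """First and pairwise moments in both the spin and occupancy bases.

    ``spin_pairs`` / ``occ_pairs`` follow the :func:`pair_indices` ordering.
    C_ij here is the raw second moment <I_i I_j> (not mean-subtracted).
    """

    spin_means: np.ndarray
    spin_pairs: np.ndarray
    occ_means: np.ndarray
    occ_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.spin_means = np.asarray(self.spin_means, dtype=float)
        self.spin_pairs = np.asarray(self.spin_pairs, dtype=float)
        self.occ_means = np.asarray(self.occ_means, dtype=float)
        self.occ_pairs = np.asarray(self.occ_pairs, dtype=float)
        n = self.spin_means.size
        if self.spin_pairs.size != n * (n - 1) // 2:
            raise ValueError("pair vector length must be N(N-1)/2")
        pairs = pair_indices(n)
        i = np.array([p[0] for p in pairs], dtype=int)
        j = np.array([p[1] for p in pairs], dtype=int)
        # affine-map consistency between the two bases
        if not np.allclose(self.spin_means, 2 * self.occ_means - 1, atol=1e-10):
            raise ValueError("spin and occupancy means inconsistent under s = 2I - 1")
        expect = 4 * self.occ_pairs - 2 * self.occ_means[i] - 2 * self.occ_means[j] + 1
        if n > 1 and not np.allclose(self.spin_pairs, expect, atol=1e-10):
            raise ValueError("spin and occupancy pair moments inconsistent")

    @property
    def n_nodes(self) -> int:
        return self.spin_means.size

    @classmethod
    def from_spin(cls, spin_means: np.ndarray, spin_pairs: np.ndarray) -> "MomentSet":
        spin_means = np.asarray(spin_means, dtype=float)
        spin_pairs = np.asarray(spin_pairs, dtype=float)
        n = spin_means.size
        pairs = pair_indices(n)
        i = np.array([p[0] for p in pairs], dtype=int)
        j = np.array([p[1] for p in pairs], dtype=int)
        occ_means = (spin_means + 1) / 2
        occ_pairs = (spin_pairs + 2 * occ_means[i] + 2 * occ_means[j] - 1) / 4
        return cls(spin_means, spin_pairs, occ_means, occ_pairs)

    @classmethod
    def from_occupancy_frames(
        cls, occ: np.ndarray, weights: np.ndarray | None = None
    ) -> "MomentSet":
        """Moments of a frames x nodes occupancy array (optionally weighted)."""
        occ = np.asarray(occ, dtype=float)
        if occ.shape[0] == 0:
            raise ValueError("empty frame selection")
        if weights is None:
            weights = np.full(occ.shape[0], 1.0 / occ.shape[0])
        occ_means = weights @ occ
        pairs = pair_indices(occ.shape[1])
        occ_pairs = np.array([weights @ (occ[:, i] * occ[:, j]) for i, j in pairs])
        spins = 2 * occ - 1
        spin_means = weights @ spins
        spin_pairs = np.array([weights @ (spins[:, i] * spins[:, j]) for i, j in pairs])
        return cls(spin_means, spin_pairs, occ_means, occ_pairs)


def _read_token_file(path: Path) -> np.ndarray:
    tokens = path.read_text().split()
    if not tokens:
        raise ValueError(f"empty occupancy file: {path}")
    try:
        vals = np.array([int(float(t)) for t in tokens])
    except ValueError as exc:
        raise ValueError(f"non-numeric token in {path}: {exc}") from exc
    if not np.isin(vals, (0, 1)).all():
        bad = vals[~np.isin(vals, (0, 1))][0]
        raise ValueError(f"non-binary value {bad} in {path}")
    return vals


def read_occupancy(
    paths: Sequence[str | Path],
    layout: str = "per-node-files",
    frame_period: float = 1.0,
    trial_length: int | None = None,
    n_trials: int | None = None,
) -> OccupancySignal:
    """Read an occupancy signal from plain-text files.

    Two dialects are supported.  ``per-node-files``: one file per node, each a
    whitespace/newline-separated stream of 0/1 tokens; node order follows the
    order of ``paths``.  ``matrix-file``: a single delimited file (whitespace
    or comma) with one frame per row, one node per column, and an optional
    non-numeric header row of node labels.
    """
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
    if layout == "per-node-files":
        columns = [_read_token_file(p) for p in paths]
        lengths = {len(c) for c in columns}
        if len(lengths) != 1:
            raise ValueError(
                f"mismatched frame counts across node files: {sorted(len(c) for c in columns)}"
            )
        values = np.stack(columns, axis=1)
        labels = list(range(1, len(paths) + 1))
    elif layout == "matrix-file":
        if len(paths) != 1:
            raise ValueError("matrix-file layout takes exactly one path")
        text = paths[0].read_text()
        if not text.strip():
            raise ValueError(f"empty occupancy file: {paths[0]}")
        raw = [ln for ln in text.splitlines() if ln.strip()]
        labels = None
        if raw[0].lstrip().startswith("#"):  # comment header of node labels
            labels = raw[0].lstrip("# ").replace(",", " ").split()
            raw = raw[1:]
        lines = [ln.replace(",", " ").split() for ln in raw]
        if labels is None:
            try:
                int(float(lines[0][0]))
            except ValueError:
                labels = lines[0]
                lines = lines[1:]
        try:
            values = np.array([[int(float(t)) for t in row] for row in lines])
        except ValueError as exc:
            raise ValueError(f"non-numeric token in {paths[0]}: {exc}") from exc
        if values.size and not np.isin(values, (0, 1)).all():
            bad = values[~np.isin(values, (0, 1))].flat[0]
            raise ValueError(f"non-binary value {bad} in {paths[0]}")
        if labels is None:
            labels = list(range(1, values.shape[1] + 1))
    else:
        raise ValueError(f"unknown layout: {layout!r}")

    provenance = {"files": [str(p) for p in paths], "layout": layout}
    logger.info(
        "read occupancy: %d frames x %d nodes from %s (%s layout)",
        values.shape[0], values.shape[1], [p.name for p in paths], layout,
    )
    return OccupancySignal(
        values=values,
        frame_period=frame_period,
        node_labels=labels,
        trial_length=trial_length,
        n_trials=n_trials,
        provenance=provenance,
    )


def write_occupancy(
    signal: OccupancySignal, out_dir: str | Path, layout: str = "per-node-files",
    stem: str = "node",
) -> list[Path]:
    """Write a signal in one of the dialects :func:`read_occupancy` accepts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if layout == "per-node-files":
        for i in range(signal.n_nodes):
            p = out_dir / f"{stem}{i + 1}.txt"
            p.write_text("\n".join(map(str, signal.values[:, i].tolist())) + "\n")
            written.append(p)
    elif layout == "matrix-file":
        p = out_dir / f"{stem}_matrix.txt"
        header = "# " + " ".join(map(str, signal.node_labels))
        body = "\n".join(" ".join(map(str, row)) for row in signal.values.tolist())
        p.write_text(header + "\n" + body + "\n")
        written.append(p)
    else:
        raise ValueError(f"unknown layout: {layout!r}")
    return written


def segment_trials(
    signal: OccupancySignal,
    trial_length: int | None = None,
    regime_split_day: int | None = None,
) -> list[TrialWindow]:
    """Split the signal into equal-length daily trials.

    Trials with 0-based index below ``regime_split_day`` are labelled regime
    "A", the rest "B"; without a split day all windows are labelled "all".
    """
    trial_length = trial_length or signal.trial_length
    if trial_length is None:
        raise ValueError("trial_length required")
    if signal.n_frames % trial_length != 0:
        raise ValueError(
            f"frame count {signal.n_frames} not divisible by trial length "
            f"{trial_length} (remainder {signal.n_frames % trial_length})"
        )
    n_trials = signal.n_frames // trial_length
    signal.trial_length = trial_length
    signal.n_trials = n_trials
    windows = []
    for d in range(n_trials):
        if regime_split_day is None:
            regime = "all"
        else:
            regime = "A" if d < regime_split_day else "B"
        windows.append(TrialWindow(d, 0, trial_length, regime))
    return windows


def stationary_slice(
    window: TrialWindow,
    start_s: float,
    end_s: float,
    frame_period: float = 1.0,
    trial_length: int | None = None,
) -> TrialWindow:
    """Restrict a trial window to [start_s, end_s) seconds within the trial."""
    if not 0 <= start_s < end_s:
        raise ValueError(f"invalid seconds range [{start_s}, {end_s})")
    start = int(round(start_s / frame_period))
    end = int(round(end_s / frame_period))
    limit = trial_length if trial_length is not None else window.end
    if end > limit:
        raise ValueError(f"slice end {end} beyond trial length {limit}")
    return TrialWindow(window.trial_index, start, end, window.regime)


def encode_states(occ: np.ndarray | OccupancySignal,
                  windows: Iterable[TrialWindow] | None = None) -> np.ndarray:
    """Encode occupancy frames as integer state codes (node 1 = LSB)."""
    if isinstance(occ, OccupancySignal):
        frames = occ.frames_in(windows) if windows is not None else occ.values
    else:
        frames = np.asarray(occ)
    if frames.ndim == 1:
        frames = frames[None, :]
    weights = 1 << np.arange(frames.shape[1], dtype=np.int64)
    return frames.astype(np.int64) @ weights


def decode_state(codes: np.ndarray | int, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`encode_states`: codes -> occupancy rows."""
    codes = np.atleast_1d(np.asarray(codes, dtype=np.int64))
    return ((codes[:, None] >> np.arange(n_nodes)) & 1).astype(np.uint8)


def empirical_distribution(
    states: np.ndarray, n_nodes: int, pseudocount: float = 0.0
) -> StateDistribution:
    """Relative state frequencies over all 2^N codes.

    ``pseudocount`` adds a Laplace-style count to every state before
    normalising (off by default; useful when some states were never seen and
    a strictly positive distribution is needed).
    """
    states = np.asarray(states, dtype=np.int64)
    if states.size == 0:
        raise ValueError("empty state sequence")
    counts = np.bincount(states, minlength=2**n_nodes).astype(float)
    if counts.size > 2**n_nodes:
        raise ValueError("state code out of range for N")
    if pseudocount:
        logger.info("empirical_distribution: applying pseudocount %g", pseudocount)
        counts += pseudocount
    return StateDistribution(counts / counts.sum(), n_nodes, origin="empirical")


def empirical_moments(
    signal: OccupancySignal, windows: Iterable[TrialWindow] | None = None
) -> MomentSet:
    """Moments over the concatenated frames of the selected windows.

    Frames are pooled across windows before averaging (plain time averages
    over the selected signal), not averaged per trial and then pooled.
    """
    frames = signal.frames_in(windows) if windows is not None else signal.values
    return MomentSet.from_occupancy_frames(frames)
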