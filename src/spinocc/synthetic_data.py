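"""Ground-truth synthetic occupancy datasets for end-to-end validation.

Generates occupancy signals with the statistical structure the analysis
assumes: a known pairwise model (h*, J*) whose stationary states follow the
exact Boltzmann law, organised into daily trials that (optionally) open with
an all-empty transient relaxing under the Monte Carlo chain — emulating a
colony leaving the nest at the start of each trial — before the stationary
plateau.  An independent-Bernoulli generator provides the J = 0 control.

Defaults mirror the reference experimental geometry: 8 nodes, 25 daily
trials of 5400 one-second frames (135 000 frames in total), ground-truth
fields h* ~ U(-1, 1) and couplings J* ~ U(-0.3, 0.3), which place per-node
occupancies roughly in the 0.3-0.6 band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mc_dynamics import run_chain_occupancy
from .occupancy_data import OccupancySignal, decode_state, write_occupancy
from .spin_glass_core import (
    ENUMERATION_CAP,
    SpinGlassModel,
    boltzmann_distribution,
    save_model,
)

__all__ = ["SyntheticSpec", "make_ground_truth", "sample_dataset",
           "sample_null_dataset", "write_dataset"]


@dataclass
class SyntheticSpec:
    """Geometry and ground-truth parameter ranges for a synthetic dataset."""

    n_nodes: int = 8
    h_range: tuple[float, float] = (-1.0, 1.0)
    J_range: tuple[float, float] = (-0.3, 0.3)
    n_trials: int = 25
    trial_length: int = 5400
    frame_period: float = 1.0
    transient_model: str = "none"  # none | mc-relaxation
    transient_frames: int = 0  # leading frames per trial generated by the chain
    frames_per_sweep: int = 50  # chain frames each sweep covers in mc modes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.trial_length < 1 or self.n_nodes < 1:
            raise ValueError("trial geometry must be positive")
        for r in (self.h_range, self.J_range):
            if not np.isfinite(r).all():
                raise ValueError("parameter ranges must be finite")
        if self.transient_model not in ("none", "mc-relaxation"):
            raise ValueError(f"unknown transient_model: {self.transient_model!r}")
        if self.transient_model == "mc-relaxation" and self.transient_frames <= 0:
            # half the trial mirrors a transient ending at mid-trial
            self.transient_frames = self.trial_length // 2


def make_ground_truth(spec: SyntheticSpec) -> SpinGlassModel:
    """Draw a ground-truth model: h ~ U(h_range), J ~ U(J_range) symmetric."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6D6F64]))
    h = rng.uniform(*spec.h_range, size=spec.n_nodes)
    n_pairs = spec.n_nodes * (spec.n_nodes - 1) // 2
    j_upper = rng.uniform(*spec.J_range, size=n_pairs)
    return SpinGlassModel.from_upper(h, j_upper)


def _exact_frames(model: SpinGlassModel, n_frames: int,
                  rng: np.random.Generator) -> np.ndarray:
    if model.n_nodes > ENUMERATION_CAP:
        raise ValueError("exact stationary sampling needs N within the enumeration cap")
    dist = boltzmann_distribution(model)
    codes = rng.choice(dist.probs.size, size=n_frames, p=dist.probs)
    return decode_state(codes, model.n_nodes)


def sample_dataset(model: SpinGlassModel, spec: SyntheticSpec) -> OccupancySignal:
    """Sample a trial-structured occupancy signal from a known model.

    Stationary frames are i.i.d. draws from the exact Boltzmann distribution
    (moment standard errors are then analytic).  With
    ``transient_model="mc-relaxation"`` each trial opens with
    ``transient_frames`` frames generated by the Metropolis chain from the
    all-empty state (each sweep held for ``frames_per_sweep`` frames),
    emulating the observed rise from I = 0 to the plateau.
    """
    root = np.random.SeedSequence([spec.seed, 0x64617461])
    streams = root.spawn(spec.n_trials)
    trials = []
    for t, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if spec.transient_model == "mc-relaxation":
            n_tr = min(spec.transient_frames, spec.trial_length)
            sweeps = int(np.ceil(n_tr / spec.frames_per_sweep))
            occ = run_chain_occupancy(model, sweeps, rng, initial_code=0)
            # sweep k's occupancy is held over [k*fps, (k+1)*fps) frames,
            # with the all-empty initial state occupying the first block
            occ = np.concatenate([np.zeros((1, model.n_nodes), np.uint8), occ])
            trans = np.repeat(occ, spec.frames_per_sweep, axis=0)[:n_tr]
            stat = _exact_frames(model, spec.trial_length - n_tr, rng)
            trials.append(np.concatenate([trans, stat], axis=0))
        else:
            trials.append(_exact_frames(model, spec.trial_length, rng))
    values = np.concatenate(trials, axis=0)
    return OccupancySignal(values, spec.frame_period,
                           trial_length=spec.trial_length, n_trials=spec.n_trials,
                           provenance={"generator": "sample_dataset", "seed": spec.seed})


def sample_null_dataset(means: np.ndarray, spec: SyntheticSpec) -> OccupancySignal:
    """Independent Bernoulli occupancy per node per frame (J = 0 control)."""
    means = np.asarray(means, dtype=float)
    if means.size != spec.n_nodes:
        raise ValueError("means length must equal n_nodes")
    if (means <= 0).any() or (means >= 1).any():
        raise ValueError("per-node means must lie strictly in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6E756C6C]))
    n_frames = spec.n_trials * spec.trial_length
    values = (rng.random((n_frames, spec.n_nodes)) < means).astype(np.uint8)
    return OccupancySignal(values, spec.frame_period,
                           trial_length=spec.trial_length, n_trials=spec.n_trials,
                           provenance={"generator": "sample_null_dataset", "seed": spec.seed})


def write_dataset(signal: OccupancySignal, model: SpinGlassModel | None,
                  spec: SyntheticSpec, out_dir: str | Path,
                  layout: str = "per-node-files") -> dict:
    """Emit the dataset in an ingestible dialect plus model file and manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = write_occupancy(signal, out_dir, layout=layout, stem="synthetic_node")
    manifest = {
        "seed": spec.seed,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in spec.__dict__.items()},
        "layout": layout,
        "files": [f.name for f in files],
        "synthetic": True,
    }
    if model is not None:
        save_model(model, out_dir / "ground_truth_model.json")
        manifest["model_file"] = "ground_truth_model.json"
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
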