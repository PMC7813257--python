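# spinocc

Pairwise maximum-entropy ("spin-glass") analysis of binary space-occupancy
time series.

## The problem

Groups of organisms — an ant colony foraging over a network of feeding
sites, for instance — leave a collective footprint in *where* they are over
time. Discretise the habitat into N meaningful sites and record, at 1 Hz, a
binary occupancy signal I_i(t) ∈ {0, 1} per site (1 = at least one
individual present). If the foragers act independently, the sites' signals
are statistically independent; if the group coordinates as a unit
("superorganism-like" behaviour), correlations between site occupancies
emerge. `spinocc` quantifies exactly that: it fits the least-structured
probabilistic model consistent with the observed single-site and pairwise
statistics, produces a generative *replica* of the occupancy dynamics, and
contrasts it with an independent-sites null model.

## The model

Map occupancies to spins, s_i = 2 I_i − 1 ∈ {−1, +1}. The pairwise
maximum-entropy model over joint states **S** = (s_1, …, s_N) is the
Boltzmann distribution

    P(S) = exp(−β H(S)) / Z,
    H(S) = − Σ_i h_i s_i − Σ_{i<j} J_ij s_i s_j,      β = 1,

where h_i is a per-site bias (attraction to site i) and J_ij a symmetric
pairwise coupling (J_ij > 0 favours sites i and j being simultaneously
occupied or empty — collective coordination). The *inverse Ising* problem —
finding (h, J) from data — is solved by Boltzmann-machine learning: gradient
ascent on the likelihood, whose update is simply the moment mismatch

    h_i  ← h_i  + η (⟨s_i⟩_data − ⟨s_i⟩_model),
    J_ij ← J_ij + η (⟨s_i s_j⟩_data − ⟨s_i s_j⟩_model),

with model moments computed by exact enumeration over the 2^N states (the
intended regime is small N; the reference geometry is N = 8, i.e. 256
states). The fitted model generates replica trials by single-spin-flip
Metropolis Monte Carlo started from the all-empty state, mirroring how each
experimental trial starts with the colony in the nest; a seconds-per-sweep
time scale is calibrated against the observed mean-occupancy rise curve.
The null model clamps J ≡ 0 (fields then have the closed form
h_i = atanh⟨s_i⟩): it reproduces every per-site mean but no correlation,
and its failure to reproduce fluctuation and persistence statistics is the
evidence that pairwise structure matters.

## Worked example

```python
import numpy as np
import spinocc as so
from spinocc.mc_dynamics import step_curve_to_seconds

# 1. generate a synthetic colony dataset with a known ground-truth model
spec = so.SyntheticSpec(n_nodes=8, J_range=(0.05, 0.35), seed=1,
                        transient_model="mc-relaxation")
truth = so.make_ground_truth(spec)
signal = so.sample_dataset(truth, spec)
print(f"dataset: {signal.n_frames} frames x {signal.n_nodes} nodes "
      f"({spec.n_trials} trials of {spec.trial_length} s)")

# 2. fit the pairwise model on the stationary window of every trial
windows = so.segment_trials(signal, 5400)
stationary = [so.stationary_slice(w, 2700, 5400, 1.0, 5400) for w in windows]
moments = so.empirical_moments(signal, stationary)
full = so.fit(moments)
null = so.fit_null(moments)
print(f"full fit: converged={full.converged} after {full.iterations_used} iterations")
print(f"max |h - h*| = {np.abs(full.model.h - truth.h).max():.4f}, "
      f"max |J - J*| = {np.abs(full.model.J - truth.J).max():.4f}")

# 3. how well does each model explain the observed state distribution?
emp = so.empirical_distribution(so.encode_states(signal, stationary), 8)
for name, res in (("pairwise", full), ("independent", null)):
    kl = so.divergence(emp, so.boltzmann_distribution(res.model))
    print(f"KL(data || {name} model) = {kl:.4f} nats")

# 4. replica trials from the all-empty state; recover a known time scale
probe = so.simulate_trials(full.model, n_trials=100, steps=108, seed=2)
reference = step_curve_to_seconds(probe.mean_occupancy_per_step(), 50.0, 5400)
ensemble = so.simulate_trials(full.model, n_trials=100, steps=108, seed=3)
cal = so.calibrate_timescale(ensemble, reference)
print(f"calibrated time scale: {cal.best:.0f} s per MC sweep")

# 5. correlation between fitted fields and observed mean occupancies
r = so.parameter_observable_correlation(full.model, moments, "h-vs-occupancy")
print(f"Pearson r(h_i, <I_i>) = {r.statistic:.3f}")
```

Output:

```
dataset: 135000 frames x 8 nodes (25 trials of 5400 s)
full fit: converged=True after 1841 iterations
max |h - h*| = 0.0283, max |J - J*| = 0.0165
KL(data || pairwise model) = 0.0016 nats
KL(data || independent model) = 0.6792 nats
calibrated time scale: 55 s per MC sweep
Pearson r(h_i, <I_i>) = 0.991
```

Reading it: from 25 trials of synthetic data the fit recovers the
ground-truth fields and couplings to a few times 0.01; the pairwise model
explains the observed 256-state distribution over 400× better (in KL) than
the independent-sites null; the time-scale grid search recovers a known
50 s-per-sweep reference to within one 5 s grid step; and the fitted fields
track the per-site mean occupancies almost perfectly — h_i really is "how
attractive site i is", while the J_ij carry the collective structure the
null model cannot express.

The same pipeline runs from the shell: `spinocc make-synthetic`,
`spinocc ingest`, `spinocc fit`, `spinocc simulate`, `spinocc calibrate`,
`spinocc stats`, and `spinocc run-all <config.yaml>` for the full
regime-wise analysis (see `spinocc --help`).

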