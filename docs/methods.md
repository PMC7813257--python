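# Methods

## Model and conventions

`spinocc` models an N-site binary occupancy signal with the pairwise
maximum-entropy (spin-glass) distribution. Occupancies I_i ∈ {0, 1} map to
spins s_i = 2 I_i − 1; the energy of a joint state S is

    H(S) = − Σ_i h_i s_i − Σ_{i<j} J_ij s_i s_j,

and P(S) = e^{−βH(S)}/Z with β = 1 (β is stored, not hard-coded, so
temperature sweeps remain possible; h and J are in units of β⁻¹, i.e.
dimensionless energies). The pair sum runs over unordered pairs i < j once;
J is stored as a symmetric matrix with zero diagonal and reported as the
N(N−1)/2 upper-triangle couplings. This is the maximum-entropy distribution
constrained to reproduce the first moments ⟨s_i⟩ and pairwise moments
⟨s_i s_j⟩ — equivalently, in the occupancy basis, ⟨I_i⟩ and the raw second
moments C_ij ≡ ⟨I_i I_j⟩, related by the affine map
⟨s_i s_j⟩ = 4 C_ij − 2⟨I_i⟩ − 2⟨I_j⟩ + 1.

Joint states are encoded as integers with site 1 as the least-significant
bit (code = Σ_i I_i 2^{i−1}; code 0 is the all-empty state). Any fixed
bijection works; this one is declared here and used consistently in every
table the package writes. Frames are indexed 0-based and windows are
half-open [start, end), which makes a "2700–5400 s" stationary window an
exact 2700-frame slice at 1 Hz with no off-by-one ambiguity.

## Data layout assumptions

The per-node-files reader assumes one whitespace/newline-separated stream
of 0/1 tokens per site, site order given by the order the paths are passed;
the matrix reader accepts whitespace- or comma-delimited rows with an
optional label header (`#`-prefixed or non-numeric). Any non-binary token
is a hard error — occupancy is accepted as defined upstream ("at least one
individual present"), never re-thresholded. Both readers record file names
and layout in the signal's provenance. Trials are equal-length daily
blocks; a frame count not divisible by the trial length is an error
reported with its remainder rather than silently truncated.

Moments are computed over the concatenated frames of the selected windows
(plain time averages over the pooled stationary signal), not per-trial
averages of averages; with equal-length windows the two coincide, and
pooling is the simpler contract.

## Fitting

Maximum-likelihood fitting of an exponential family by moment matching:

    h_i  ← h_i  + η (⟨s_i⟩_data − ⟨s_i⟩_model),
    J_ij ← J_ij + η (⟨s_i s_j⟩_data − ⟨s_i s_j⟩_model).

The log-likelihood is concave, so with a small enough step this converges
to the unique moment-matching model. Defaults: learning rate η = 0.1,
tolerance 10⁻⁶ on the maximum absolute spin-moment mismatch, iteration cap
50 000, initialisation at the independent-sites warm start
h_i = atanh⟨s_i⟩, J = 0. At N = 8 these defaults converge in a few
thousand iterations (milliseconds per iteration with enumerated moments)
and recover ground-truth parameters from exact moments to ≲ 10⁻⁴.

Model moments come from exact enumeration of the 2^N states up to a cap of
N = 20 (~10⁶ states — a memory/exactness balance); above the cap the
package refuses enumeration and offers a persistent-chain Monte Carlo
gradient mode (tolerance default 10⁻³ there, reflecting sampling noise).
Mean-field/TAP/pseudo-likelihood approximations for large N are out of
scope by design.

The fit trace records the per-frame negative log-likelihood
log Z − h·⟨s⟩_data − J·⟨ss⟩_data, which equals KL(data‖model) up to the
data-entropy constant; the reported divergence between explicit state
distributions is KL(empirical‖model), the quantity maximum-likelihood
descent minimises. Saturated empirical moments (|⟨s_i⟩| = 1, or a
deterministic pair) would drive fields to infinity; they raise an error
pointing at the optional Laplace pseudocount on the state histogram (off
by default, logged when used).

The null model clamps J ≡ 0 and learns only h (convergence is then judged
on the field moments alone, since pair moments are deliberately not
fitted). Each null field has the closed form h_i = atanh⟨s_i⟩, which the
iterative result is cross-checked against; the null distribution
factorises over sites, reproducing every marginal and no correlation.

## Monte Carlo dynamics and time scale

Replica dynamics use single-spin-flip Metropolis: one simulation step is
one sweep of N random-site flip attempts, each accepted with
min(1, e^{−βΔH}). A Glauber (heat-bath) kernel is exposed as an option;
both satisfy detailed balance for P(S) and differ only in relaxation
speed, which the time-scale calibration absorbs. Sweeps (rather than
single attempts) are the step unit so that a seconds-per-step factor is
comparable across N. Every trial starts from the all-empty state,
mirroring the experimental protocol in which each trial begins with the
colony in the nest. Per-trial RNG streams are spawned deterministically
from one master seed (`numpy` SeedSequence), so ensembles are exactly
reproducible and trivially parallelisable.

Mapping sweeps to seconds: the calibration grid-searches a
seconds-per-sweep factor (default grid 5–300 s in 5 s steps), mapping the
per-sweep ensemble mean occupancy to the reference curve's 1 Hz sampling
piecewise-constantly — sweep k holds on [k·a, (k+1)·a) with the initial
all-empty state on [0, a) — and scoring by the sum of squared differences
over the whole trial; ties break to the smaller scale. On reference curves
built at a known scale from an independent run, the search recovers the
scale to within one grid step.

## Comparison statistics

- Trajectory statistics: ⟨I⟩(t) averaged over sites and trials; the
  fluctuation band is the across-trial standard deviation of the
  site-averaged occupancy using the population (divide-by-n) convention —
  it is a descriptive band, and fixing the convention makes tests exact.
- Persistence times: per site and trial, run lengths of constant state.
  Runs touching a window boundary have unknown true length and are
  censored (dropped) by default, with counts recorded in the result; a
  keep-boundary option exists. Distributions are emitted both raw and
  log-binned, since the natural binning of P(τ) is use-dependent.
- Parameter–observable correlations: Pearson r between h_i and ⟨I_i⟩
  (N points) and between J_ij and C_ij (N(N−1)/2 points). Note that the
  raw second moment C_ij is dominated by the product of means when site
  means vary widely; in that regime only the connected part
  C_ij − ⟨I_i⟩⟨I_j⟩ is sharply diagnostic of J (the test suite checks the
  connected version on synthetic round trips, r > 0.8 at 10⁵ frames,
  alongside r > 0.95 for h vs ⟨I_i⟩).
- Group contrasts: Welch's two-sample t-test by default (the robust
  choice when within-group variances differ); two-sided p-values are
  reported — halve for a one-sided reading. Curve-level comparisons use
  one-way ANOVA at matched time/τ points. High/low site partitions are
  always user input, never inferred from the data.

## Synthetic data: what it emulates, and what it does not

The generator draws a ground-truth model (defaults h* ~ U(−1, 1),
J* ~ U(−0.3, 0.3), placing site occupancies roughly in the 0.3–0.6 band)
and emits trial-structured datasets at the reference geometry: 8 sites,
25 daily trials of 5400 frames at 1 Hz (135 000 frames). Stationary frames
are i.i.d. draws from the exact Boltzmann law — the fit only targets
single-time moments, and i.i.d. sampling makes their standard errors
analytic. A chain-sampled mode exists where temporal statistics matter.
With the `mc-relaxation` transient, each trial opens with a Metropolis
relaxation from the all-empty state, each sweep held for a fixed number of
frames (default 50), reproducing the observed rise of ⟨I⟩ from 0 to its
plateau.

Limitations to keep in mind when interpreting green tests. (i) The
transient chain approaches but need not exactly attain stationarity at
the switch to i.i.d. sampling; for strongly coupled models this leaves a
small discontinuity in the rise curve, which biases *data-referenced*
time-scale calibration toward smaller scales — the calibration check
therefore uses a reference built at a known scale from an independent
simulation. (ii) i.i.d. stationary frames have geometric persistence
times by construction; real signals need not. (iii) The generator does
not emulate individual movement, travel times between sites, or resource
dynamics — interaction is all-to-all in model space. Passing round-trip
tests therefore demonstrates correctness of the inference machinery under
the model's own assumptions, not that any particular real system satisfies
them.

For the null-model contrast, the data-generating truth uses net-positive
couplings J* ~ U(0.05, 0.35): the contrast is a statement about cohesive,
positively correlated occupancy — the regime the method targets — and
with mixed-sign couplings the site-averaged fluctuation signal partially
cancels. The contrast statistics are the stationary mean of the
across-trial sd curve and the mean persistence time; "Monte Carlo standard
error" is estimated as the spread of these statistics across replicate
ensembles of the data-generating model itself.

## Problem sizes

Unit and property tests run at N ≤ 8 with 10³–10⁶ frames or sweeps;
the acceptance script uses the full reference geometry (25 × 5400 frames,
10⁶-sweep chains, 100-trial ensembles with 16 replicates for the
σ estimate) and completes in well under a minute on one core. Exact
enumeration at N = 8 involves 256 states, so nothing in the default
pipeline is remotely expensive; the binding constraint is statistical
(frames), not computational.
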