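# Methods

## Model

Residence times for one residue are modeled as i.i.d. draws from a
K-term exponential mixture p(t|π,λ) = Σₖ πₖ λₖ e^(−λₖt).  The model
assumes contacts are generated by a small unknown number of memoryless
processes (distinct binding poses, partial contacts, cutoff flicker),
each contributing a single exponential.  It does not model censoring
(events cut off by the trajectory end) or correlations between
successive events.

Priors are conjugate throughout: Dirichlet(γ) on π, independent
Gamma(αₖ, βₖ) on each rate, categorical on the latent indicator zₙ.
With a latent indicator the conditional posteriors are available in
closed form, so the Gibbs sampler draws directly (no accept/reject
step): per iteration, z from its categorical conditional, π from
Dirichlet(γ + Ω), then each λₖ from Gamma(αₖ + Ωₖ, βₖ + Tₖ), in that
fixed order.  The hyperparameters act as pseudo-counts added to
(Ωₖ, Tₖ); at the 10³–10⁵ event counts this package targets, the
likelihood dominates and the exact prior values matter little.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| cutoff | 7 Å | contact distance for event extraction (coarse-grained beads) |
| frame_interval | 1 ns | time per trajectory frame; the only unit conversion |
| K | 15 | mixture-size upper bound; behaves like ∞ for K ≫ K′ |
| αₖ, βₖ | 1, 3 ns | broad Gamma prior on rates, mean 1/3 ns⁻¹; β is conjugate to a rate in ns⁻¹, so changing the time unit rescales β |
| γₖ | 1/K | Dirichlet-process-like weight prior, keeps results K-independent |
| n_iter / burn_in / thin | 110 000 / 10 000 / 100 | gives w = 1000 kept samples |
| weight numerator | 10 | per-sample filter πₖ ≥ 10/Ω (≥ ~10 expected events) |
| noise threshold | 0.4 | cluster k′ is noise iff maxₙ p_{n,k′} < 0.4 |
| density spacing | 1 Å | voxel edge of the weighted density grids |

Initialization uses uniform weights and rates log-spaced over
[1/max t, 1/min t]; any feasible start converges to the same posterior
(checked by an initialization-insensitivity test), so the choice only
affects burn-in length.

## Post-processing

The mixture posterior is invariant under index permutations, so raw
component indices are meaningless across samples.  Per sample,
components with πₖ < 10/Ω are dropped; K′ is the modal survivor count
(ties broken upward — losing a rare slow cluster is the costlier
error).  Samples with exactly K′ survivors train a K′-component
full-covariance Gaussian mixture in (log λ, log π); the fitted mixture
then partitions all surviving components of all samples (a many-to-one
map).  Training points are sorted lexicographically before fitting so
the result cannot depend on component order within samples; the GMM
seed comes from the run config with 10 restarts.  Clusters are
re-indexed by decreasing MAP rate (fastest = 0).

Event memberships p_{n,k′} are the fraction of kept samples whose
mapped indicator for event n is k′.  Rows may sum to < 1; the deficit
(samples in which the event's component was weight-filtered) is
reported as unassigned mass rather than renormalized, since
renormalizing would overstate confidence.

MAP estimates are histogram modes: Freedman–Diaconis binning, capped
at 1000 bins and at the float resolution of the data, falling back to
50 bins for degenerate IQR; ties go to the lower-valued bin and a
sample is flagged multimodal when two half-height peaks are separated
by a sub-half-height valley.  Intervals are 2.5/97.5 percentile
intervals (not HPD).  Residence times are obtained by histogramming
the reciprocals of the rate samples — MAP(τ) ≠ 1/MAP(λ) in general
because of the Jacobian — while the τ interval endpoints are the
reciprocals of the swapped rate percentiles (exact for a monotone
decreasing transform).  MAP estimation requires ≥ 20 samples;
internal cluster summaries fall back to the median below that.

The per-residue fingerprint reports τ = max over non-noise clusters of
MAP τ, flagging residues with τ at least four times the table mean.

## Event extraction

A contact exists in a frame when the minimum residue–ligand distance
is ≤ cutoff (boundary inclusive); each maximal contiguous in-cutoff
run is one event with duration = run length × frame_interval.  A
single-frame contact has duration one frame_interval, not zero (zero
durations break the exponential likelihood).  A ligand that leaves and
re-enters starts a new event — no hysteresis or gap tolerance.  Events
still in contact at the final frame are retained at their observed
duration and flagged censored; excluding them would bias against
exactly the long events of interest, and the likelihood has no
censoring term, so flagged durations are lower bounds.

## Kinetic mapping and weighted densities

Hard assignment gives each event (and its frame range) the argmax
cluster of its membership row, ties broken toward the slower cluster;
an all-zero row is labeled unassigned.  Weighted densities histogram
ligand particle positions on a cubic grid (half-open voxels
[edge, edge + spacing)), each frame weighted by its event's p_{n,k′}.
The grid origin is the padded coordinate minimum snapped down to the
spacing lattice, making grids reproducible; density = weighted counts
/ (Σ frame weights × voxel volume), with the normalization constant
stored so counts can be recovered.  Per-cluster counts plus the
unassigned-mass counts equal the unweighted histogram voxel by voxel.
Ligand identity is erased across events: all copies of the same
chemical species contribute to one density.

## Synthetic data

The generator draws a component per event from π, then a duration from
Exp(λₖ) — exactly the generative model.  The default scenario is three
components, π = (0.9, 0.09, 0.01), λ = (5, 0.5, 0.05) ns⁻¹, rates an
order of magnitude apart, at n = 5 × 10⁴ — a dominant flicker process,
an intermediate one and a rare slow one, which is the regime the
method is built to resolve.  Labels are returned for validation only
and never passed to inference.  The toy distance-series builder
realizes explicit in/out patterns with jitter bounded away from the
cutoff, so event extraction recovers the pattern exactly.

What the generator does not emulate: correlated or non-exponential
event durations, censoring at trajectory boundaries, multiple
residues sharing ligands, or spatially realistic coordinates (density
tests use labeled Gaussian blobs).  Passing tests therefore
demonstrate correct inference *given the model*, not that real contact
series are hyperexponential.

## Numerical choices

- Indicator probabilities are computed in linear space with a
  log-space (max-shift) fallback when all terms underflow; λₖtₙ can
  exceed 700 for flicker components on long events, and the contract
  is no NaN for tₙ up to 10⁶ ns with λ up to 10² ns⁻¹.
- The Gibbs inner loop is a numba-compiled kernel doing O(ΩK) work per
  iteration with a single seeded generator; draws occur in a fixed
  order, so identical (data, seed, config) give bit-identical chains.
  The driver runs the kernel in chunks only to emit progress logs;
  chunking does not change the stream.
- Kept-sample count w = ⌊(n_iter − burn_in)/thin⌋; partial tail
  iterations are discarded.
- Dirichlet draws are normalized Gamma draws inside the kernel.

## Test design and problem sizes

The test suite exercises recovery at reduced scale so it runs on a
desk machine: single-exponential recovery at Ω = 10⁴, two-component
recovery at Ω = 3000–4000 with chains of 4000–11 000 iterations, and
the three-component scenario at Ω = 10⁴ with 30 000 iterations.
Burn-in/thinning/initialization/K insensitivity are asserted as
overlapping 95% intervals across paired runs at these sizes.
`scripts/acceptance.py` runs the full-scale validation
(Ω = 5 × 10⁴, 110 000 iterations, ~10 minutes on one core).
Post-processing correctness (label-switching invariance, membership
counting, noise boundaries) is checked on chains constructed directly
from known centroids with per-sample permutations, against
nearest-centroid and naive-loop oracles.

## Known limitations

- No censored-data likelihood: τ for residues whose longest events hit
  the trajectory end is underestimated; the censored flags make such
  cases visible.
- The weight filter (10 expected events) makes components rarer than
  ~10/Ω invisible by construction; with fewer than ~10³ events the
  slow component of the default scenario is not reliably resolved.
- MAP-by-histogram has bin-width resolution; multimodal marginals are
  flagged but not resolved.
- Components closer than about an order of magnitude in rate merge
  unless the dataset is large.
- The GMM label correction assumes clusters are roughly Gaussian in
  (log λ, log π); heavily overlapping posteriors may split or merge
  clusters, which surfaces as noise flags or widened intervals.
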