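# Methods

## Study design assumed

`cyclenet` analyzes gene × sample TPM matrices from a replicated circadian
design: two independent experiments (labelled V1 and V2) profiled under
two conditions (18°C and 25°C), sampled at regular ZT times (hours since
lights-on) across a stable window — by default every 2 h over 48 h, i.e.
24 timepoints covering two full cycles.  Replicate samples at a timepoint
enter all fits as independent observations.  The interaction network is an
undirected simple graph over gene identifiers, consumed as a two-column
edge list (e.g. an export of a pathway-database graph); the package never
builds such a graph from a database itself.

## Expression filter

A gene enters the analysis universe when its median TPM across all
samples of a condition exceeds 5 in at least one condition, *consistently
in every experiment* (AND over experiments of OR over conditions — the
reading under which "consistently" binds the experiments).  The median is
per experiment, uses all timepoints and replicates, and the threshold is
a strict inequality (a median of exactly 5 fails).  The filter is
idempotent and invariant to sample order.

## Rhythm detection

The cosinor model `y(t) = m + a·cos(2π(t−φ)/T)` with T fixed at 24 h is
fit by OLS in its linear form.  Design choices:

* **Fixed single harmonic.**  No period scan and no second harmonic; the
  design samples two full periods, which identifies the 24 h component
  cleanly.
* **Raw TPM by default.**  A `log_transform` flag (log2(TPM+1)) exists
  but is off by default.
* **F-test.**  The two harmonic coefficients jointly, F(2, n−3).  An
  exactly constant series returns amplitude 0, undefined phase and p = 1
  by convention, keeping the pipeline total; a perfectly fit sinusoid
  returns p = 0.
* **No multiple-testing correction** on the per-experiment p < 0.1.
  Replication across experiments is the error control: the expected
  chance-call count `N·p²·(Δφ_max/12)` quantifies it (16.935 for
  N = 6774, p = 0.1, Δφ_max = 3 h), and `false_discovery_summary`
  converts it to per-condition FDR percentages.

Phase differences use the standard circular distance
`min(|φ₁−φ₂| mod 24, 24 − |φ₁−φ₂| mod 24)` ∈ [0, 12] h.  The consensus
phase of a called gene is the circular mean of its two experiments'
estimates; a circular mean with resultant length below 1e−9 (antipodal
input) is flagged undefined (NaN) and callers decide.

## Phase-distribution analyses

* **KS comparisons** linearize the circle at a configurable cut (default
  ZT0, lights-on).  The statistic depends on the cut, so the cut is
  echoed in every result.
* **Density peaks** use a von Mises kernel of concentration κ = 8
  (kernel SD ≈ 1.35 h), chosen to resolve peaks ≥ 4 h apart, on a 0.1 h
  grid.  A peak must be a strict local maximum, reach 50% of the global
  maximum, and exceed 1.2× the mean density — the last condition
  suppresses the spurious wiggles of a flat sample.
* **Signed phase shift** between conditions is `phase_25 − phase_18`
  wrapped to (−12, 12]; positive means the gene peaks earlier in the
  cold.  Computed only on genes called cycling in both conditions.
* **Variance and amplitude comparisons** are two-tailed Wilcoxon
  signed-rank tests on per-gene paired values.  Variance pools V1 and V2
  samples of a condition by default (a per-experiment mode is available
  by passing unpooled matrices); amplitude per condition is the mean of
  the two experiments' fitted amplitudes.  All-zero differences return
  p = 1 with a warning; fewer than 2 pairs is an error.

## Network phase organization

All graph analyses run on the largest connected component (LCC; size
ties broken toward the component containing the lexicographically
smallest node).  Distances are unweighted BFS hop counts, computed as an
all-pairs matrix via sparse-graph BFS.

Sanity checks before the main test: the cycling genes on the network
should be phase-representative of all cyclers (KS), their degree
distribution unremarkable (two-sample KS — the test here is a documented
choice), and their pairwise distances smaller than the all-pairs
background (one-sided Wilcoxon rank-sum; above a 10⁷ pair ceiling a
seeded uniform subsample is used and reported).

The main statistic is the **median Δφ per geodesic-distance class**
among cycling genes.  Classes with fewer than `min_pairs` pairs (default
50) are dropped because medians of sparse classes are unstable, and
`d_max` defaults to every sufficiently populated class.  The trend is an
unweighted OLS of the per-class medians on distance (one point per
class); a perfectly flat profile returns slope 0 with p = 1 by
convention.  A pair-level regression is deliberately not the default:
the class medians are the quantity of interest and pair-level residuals
are heavily dependent.

The **permutation null** re-draws the cycling genes' positions uniformly
without replacement from the LCC (default 5000 permutations) and
attaches the observed phase multiset to the drawn positions in random
order — equivalent marginally to shuffling phases, but positions-based
matches the hypothesis being tested (where cyclers sit, not what phases
exist).  Each permutation preserves the number of cyclers and the phase
multiset by construction.  Per class the one-sided empirical p is
`(1 + #{null median ≤ observed}) / (1 + n_perm)` (a "greater" and a
two-sided variant exist), so p ∈ [1/(n_perm+1), 1] and is exactly
uniform under the null.  Distance classes empty in a permutation are
recorded as missing for that permutation, never as zero.

## Synthetic-data generator

The generator emulates the assumed study design with known ground truth:

* **Network**: Erdős–Rényi, Watts–Strogatz or Barabási–Albert graphs
  over synthetic gene IDs (a stand-in for a pathway-derived graph);
  parameters that leave a model undefined (odd ring-lattice degree) are
  rejected.
* **Phase planting**: `round(frac_cycling·|V|)` uniformly chosen nodes
  get phases uniform on [0, 24), then `n_smooth` rounds of circular
  relaxation pull each cycling node's unit phasor toward the mean phasor
  of its cycling neighbours with weight `coupling`.  This iterated local
  averaging (rather than an explicit random-field model) is simple,
  controllable, and produces the distance-decaying phase similarity the
  network test targets.  Note the regime matters: when the
  cycler-induced subgraph is densely connected, strong coupling
  synchronizes phases *globally*, which removes the contrast the test
  measures; organization is detectable when cyclers are a sparse
  minority forming locally coherent patches.
* **Expression**: `mesor + amplitude·cos(2π(t − φ − ε)/24)` for cyclers
  (flat genes sit at their mesor), where ε ~ N(0, 0.5 h) is a per-gene,
  per-experiment phase jitter mirroring the inter-experiment
  replication logic.  Mesors are lognormal with median 50 TPM (σ = 0.6),
  so nearly all genes clear the TPM-5 filter; cycling amplitudes are a
  uniform 0.3–0.8 fraction of the mesor — moderate, detectable relative
  amplitudes.  Noise is multiplicative lognormal with unit mean and
  CV 0.2 by default (the analysis operates on TPM directly; a
  count-level noise model is out of scope), and values are clipped at 0
  as a guard.  Replicate count defaults to 1 and is configurable.
* **Determinism**: one master seed feeds named substreams (network /
  planting / noise, the last salted by experiment and condition), so
  each stage is independently reproducible and experiments get
  independent noise.

What the generator does **not** emulate: count-level sampling noise,
alternative splicing, batch effects beyond inter-experiment jitter, or a
realistic pathway-graph topology.  Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under the stated
model, not that any particular biological dataset will show organization.

## Numerical and degenerate-input choices

* Phases are reported mod 24 in [0, 24); floating-point residue that
  would round a mod result to exactly 24 is snapped to 0.
* Harmonic fits require ≥ 4 distinct timepoints (mod period); a design
  degenerate mod period raises.
* Circular correlation and circular means flag degenerate inputs (zero
  resultant / zero circular variance) as NaN rather than guessing.
* Empirical p-values use the add-one estimator and never equal 0.

## Problem sizes used in the test suite

Statistical tests run at sizes chosen to give stable verdicts at desk
scale: null calibration of the dual criterion at the full 6774-gene
universe over 200 replicate studies; permutation-test calibration and
power at 100 simulated datasets on a 500-node graph with 100 cyclers and
500 permutations each; oracle equivalence of the circular distance on
10⁶ random pairs and of BFS distances on ≤ 300-node graphs.

## Known limitations

* The KS test on circular data depends on the cut point; results report
  the cut, but cross-study comparisons should fix it.
* The degree-comparison test is a KS on discrete degrees, which is
  conservative under heavy ties.
* The permutation null conditions on the observed phase multiset; it
  tests placement, not the phase distribution itself.
* Condition labels "18C"/"25C" are conventions of the assumed design;
  nothing in the machinery is temperature-specific.
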