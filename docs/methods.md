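# Methods

## Model

The domain is a circle of radius `R` (default 30): its circumference stands in
for gray matter, its interior for white matter.  `N_n` node centers (default
84, the size of a standard whole-brain cortical+subcortical parcellation) are
placed at equal angular spacing, then displaced along the circumference by
`eps ~ rho * U(-pi/N_n, pi/N_n)` with `rho = 1` by default — the maximum
heterogeneity that still preserves the cyclic node order.  Node regions are
the 1D Voronoi cells of the perturbed centers on the perimeter; the perturbed
centers (not the geometric centroids of the resulting arcs) act both as force
sources and as assignment anchors.

Axon growth cones feel the net force

    F(s) = sum_i (R_i - s) / |R_i - s|^(beta + 1)

so one node at distance `d` attracts with magnitude `d^-beta`.  `N_a` axons
(default 2e5) are seeded uniformly at random on the circumference and extended
in constant steps of length `L_s` in the direction of the net force, with the
turn between consecutive steps clamped to `theta` (default 15 degrees).  An
axon terminates when its step segment crosses the circle (the endpoint is the
analytic segment-circle intersection) and is abandoned as unsuccessful after
`S_max = ceil(3 R / L_s)` steps — at small `beta` a central "black hole"
region traps axons in closed orbits, and `S_max` bounds that cost.  Weights
are axon counts per region pair; within-region connections are discarded but
counted.

Conventions the growth rule needs but that follow no single canonical choice
(each is a measure-zero or start-of-trajectory case):

- **First step** follows the normalized net force at the seed, unclamped (no
  previous direction exists).  A zero net force at the seed falls back to the
  inward radial direction; a zero force mid-trajectory keeps the previous
  heading.
- **Termination testing** applies to every step segment but excludes the
  seed itself (intersections at `t <= 1e-9 R` along the segment), so an axon
  cannot "terminate" where it was born; with `L_s > 2R` an axon can still
  legitimately cross to the far arc in one step.
- **Antiparallel clamp ties** rotate counterclockwise.
- **Assignment ties** (a point exactly on a Voronoi boundary) go to the lower
  node index.
- A growth cone within `1e-12 R` of a node center makes the force singular;
  the axon is dropped as unsuccessful.
- The terminal partial step obeys the `theta` clamp like any other step.

The random-walk null model replaces the force rule with i.i.d. turns
`U(-theta, theta)`; the first direction is drawn uniformly over the inward
semicircle at the seed.  Everything else (seeding, step length, termination)
is unchanged, and `L_s = 1` is the null's standard setting.

Randomness is organized as named substreams of one top-level seed (layout
perturbation, axon seeding, null-model turns), so runs are reproducible from
their manifest and results do not depend on batch size or evaluation order.
Model growth itself is deterministic given the seed points.  The batch
stepper is a numba kernel; a pure-Python scalar stepper mirrors its
arithmetic term for term (including the exact-reciprocal fast path the kernel
uses when `beta == 1`) and serves as its independent reference in tests.

## Edge and node statistics

Weight analyses operate on strength-normalized weights
`w'_ij = w_ij / ((s_i + s_j)/2)`, which are invariant to global rescaling of
the counts.  The weight-distance association is the Pearson correlation
between edge Euclidean lengths and log10 normalized weights.  Distribution
fitting compares lognormal, gamma, normal, exponential and Weibull families,
each maximum-likelihood fitted on the natural scale (location pinned to 0 for
the positive-support families so all five share a common support) and ranked
by the one-sample KS statistic.

The scale-free test follows the Clauset procedure for the discrete power law

    P(K) = K^-alpha / zeta(alpha, K_min)        (Hurwitz-zeta normalizer)

`alpha` is estimated per candidate `K_min` by discrete maximum likelihood on
a dense grid (1.01 to 8, step 0.01) with parabolic refinement — equivalent to
a numerical optimizer at these sample sizes but vastly cheaper inside the
bootstrap; `K_min` minimizes the tail KS distance, with candidates restricted
to leave at least 10 tail observations.  The goodness-of-fit p is a
semi-parametric bootstrap: each replicate resamples the sub-`K_min` body
empirically and the tail from the fitted model (exact inverse-CDF sampling
from a precomputed survival table), refits from scratch, and records its KS;
`p` is the fraction of replicates at least as discrepant as the data, with
rejection at `p < 0.1` and a population deemed plausibly scale-free when more
than half its members reach `p >= 0.1`.  `n_boot` defaults to 1000 and is
reduced in desk-scale tests (250), where the verdict fractions are far from
the Monte-Carlo noise floor.

A calibration caveat established while validating this module: on binomial
(ER-like) degree sequences of length 300 the Clauset test has essentially no
power — KS minimization retreats to a narrow upper tail that a steep power
law mimics, so such populations sit near the 50% plausibility boundary
rather than being clearly rejected.  This matches the behavior of the
independent plfit implementation and is a property of the test at this
sample size, not of this package.

## Topology

Metrics follow the weighted-undirected conventions of the standard brain
connectivity toolbox: clustering is the geometric-mean triangle intensity on
max-normalized weights (nodes with degree < 2 score 0); path lengths use the
`1/w` connection-length transform with CPL averaged over finite ordered
pairs (disconnected pairs are excluded and flagged rather than made
infinite); modularity is Newman's weighted Q maximized by Louvain with 10
seeded restarts (Q variance across restarts is negligible at n = 84).
Before topology, networks are thresholded to an analysis density (default
10%, strongest edges kept, lexicographic tie-break) and linearly rescaled to
a common total connectivity (default 2e5), making networks of different raw
density and scale comparable.

Null networks preserve the degree sequence exactly (double-edge swaps, 10x
edge-count attempts) and the weight multiset exactly; weights are reassigned
by iterative rank-matching against residual strength products, which keeps
null strength sequences correlated > 0.9 with the originals.  Normalized
metrics are ratios to the null mean over `n_nulls` surrogates (default 20;
reduced in desk-scale runs), and `SW = (CC/CC_null) / (CPL/CPL_null)`.

Grid evaluation ("landscapes") simulates one network per (beta, L_s) cell per
landscape, sharing the node perturbation and axon seeding across cells within
a landscape (common random numbers), and averages metrics across landscapes.
Cells whose raw density falls below the analysis density are flagged and
excluded.

## Parameter fitting

A target connectome (any square symmetric nonnegative matrix) is pushed
through the same threshold/rescale/normalize pipeline as model networks; the
objective is

    RMSE = sqrt( mean( ((m_X - t_X) / sd_X)^2 ) ),  X in {CC, CPL, Q}

(SW is excluded as a function of CC and CPL; dividing by 3 rather than
another positive constant does not move any argmin).  The default grid is
101 x 101 over 0.99 <= beta <= 1.01, 0.1 <= L_s <= 2.1 with 50 landscapes;
per landscape the argmin cell is recorded and the fitted parameters are the
mean of the per-landscape optima.  `metric_sds` standardizes the three
errors; it defaults to unit SDs, and `estimate_metric_sds` derives them from
a pilot population of model networks at the grid center when no empirical
cohort is available — without standardization the (noisiest) clustering term
dominates the objective.

## Scale choices and what the tests show

Desk-scale protocols used by the test suite: density sweeps run at the full
N_a = 2e5 with three seeds per setting; parameter recovery uses a 5 x 5 grid
over the full default ranges, N_a = 2e4 and 5 landscapes; scale-free
calibration uses 100 sequences of n = 300 with 250 bootstraps; topology
trends use a 3 x 3 grid at N_a = 5e4 with 2 landscapes and 10 nulls.

Two properties of the model worth knowing when interpreting results.  First,
connectivity density at fixed parameters varies substantially across layout
realizations (e.g. at beta = 1, L_s = 1: sd ~1.5 percentage points, observed
range 18-24% over 20 seeds; at L_s = 2: sd ~2.6, range 35-43%), so
single-realization density figures carry several points of uncertainty.
Second, normalized topology metrics depend systematically on N_a (count
discreteness changes the thresholded weight profile), so targets and model
networks must be compared at matched axon counts; recovery of L_s from a
single noisy target realization is limited by the target's own realization
noise, consistent with the broad per-individual parameter spread this kind
of fitting produces on empirical cohorts.

The synthetic-target generator runs the model itself, so fitting tests
demonstrate internal consistency (parameter recovery), not agreement with
any empirical connectome; real connectomes additionally feature
hemispheric/atlas structure, measurement noise and node correspondences the
circular analogue does not model.
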