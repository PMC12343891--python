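# Methods

## Data model and normalisation

The engine operates on an events × dimensions matrix whose retained values
all lie in the closed interval [0, 1].  Fluorescence data are expected on a
logicle (biexponential) display scale — approximately linear through zero,
logarithmic at high signal — parameterised by decades M (default 4.5),
width W in decades (typically 0.5–1.55) and a top-of-scale value that maps
to exactly 1.0.  Mass-cytometry data use the W = 0, M = 4.3 member of the
same family, which is a rescaled arcsinh; small integer counts land in the
first decade as an emergent property of the map, with no special casing.
The forward map is evaluated by inverting the closed-form biexponential
with vectorised bisection (80 halvings on [−1, 2]), so the round trip is
identity to well below 1e−9.  Any event with a value outside [0, 1] or a
non-finite value in a declared dimension is censored (dropped and counted)
on input; downstream stages therefore never bounds-check.

Delimited input may be declared already transformed (`kind: none`), which
is how all synthetic tests run.  A minimal FCS 3.0/3.1 float list-mode
reader and writer is included.

## Dimension qualification

A dimension whose marginal is a single near-normal blob (uniform positive
or negative stain) cannot contribute a split.  The divergence of the
sample from a moment-matched normal is estimated by discretising onto 256
equal-probability bins of the fitted reference and computing
Σ p log(p/q) in nats with a +0.5 pseudo-count.  The estimator's null
expectation is roughly (B−1)/(2n) ≈ 0.006 at n = 20,000, comfortably
below the 0.04 working threshold, while a two-mode marginal with 4-sd
separation scores ≈ 0.17; the thresholds therefore separate the two
regimes with large margin (verified by Monte Carlo in the test suite).
In mass-cytometry mode the non-zero values are additionally compared to a
moment-matched exponential (threshold 0.2), and a dimension must diverge
from **both** references to qualify — an exponential-looking negative
dimension diverges strongly from normal yet is still uninformative.
Populations below 50 events return divergence 0 (never qualify); the
recursion has invariably stopped before this matters.

Pair enumeration: all unordered pairs of qualified dimensions, sorted by
index.  With exactly one qualified dimension it is paired with the most
normal-divergent unqualified one; with none, the two most divergent
dimensions form a single pair — at least one pair is always examined.

## Density estimation

Events are linear-binned (bilinear weights to the four enclosing grid
nodes) onto a fixed 257 × 257 grid; node (i, j) represents
(i/256, j/256).  The kernel density estimate is the symmetric-convolution
smooth of the weight array with a discretely sampled Gaussian, computed
via the type-I DCT, whose eigenbasis diagonalises convolution under
whole-sample symmetric (reflective) extension.  Because the kernel is
applied as the DCT of its sampled taps, the result equals direct
space-domain convolution with reflected padding to machine precision —
the test suite asserts sup-norm ≤ 1e−6 against that oracle and observes
~1e−15.  The density is normalised to integrate to 1 (trapezoid rule)
with the scale factor retained for the variance bookkeeping below.

The initial kernel sd is W = 0.01 of full scale (0.025 for mass data);
below 1/256 the grid cannot resolve the kernel and the request is
rejected.  Whenever the resulting partition is too complex (below), W is
widened by √2 and the smooth recomputed from the same weights.  The
previous density is retained across a widening because the squared-kernel
smooth needed by the dip test at sd W is exactly the plain smooth at
W/√2.  A cap of 8 widenings (configurable) guards pathological inputs;
at the cap the pair is abandoned for this population.

## Modal clustering

Grid points are visited in descending density order (ties broken by
row-major index, making the scan fully deterministic).  A point none of
whose 4-neighbours belongs to a cluster founds a new cluster — it is a
local maximum; a point whose 4-neighbours span two distinct clusters is
marked a boundary point; otherwise it inherits its neighbour's cluster.  A
point adjacent only to boundary points extends the boundary (founding a
mode against a valley line would create spurious micro-clusters).  As each
point is classified, seven of its eight surrounding points are marked
contiguous with the classified set; the omitted diagonal rotates NE → SE →
SW → NW with a counter modulo 4, keeping the marking radially symmetric.

New clusters may only be founded at densities above a counting-noise
floor: sliding a window of round((4W·256)²) grid points (the kernel spot
± 2W) along the density-sorted points from the bottom, the floor is the
top density of the first window holding more than σ² events (σ = 3, i.e.
9 events).  If no window qualifies the pair has no clusters and is
dropped.  Points below the floor are then absorbed layer by layer: each
sweep classifies exactly the points currently marked contiguous with the
classified set (the frontier is snapshotted per sweep so absorption grows
in equidistant layers rather than cascading in scan order), until every
point is labelled.  More than 12 clusters triggers kernel widening.

### Cluster graph

Boundary points adjacent to exactly two clusters are grouped by cluster
pair and split into 8-connected chains — the graph's edges; points
adjacent to three or more clusters form the vertices; chains may also
terminate on the grid border (treated as degree-1 virtual vertices).  The
construction validates a generalised Euler relation V − E + F = 1 + C
(exterior face, border arcs and a phantom vertex per closed curve
included; for the usual connected case this is the classic V − E + F = 2)
and raises the widening signal on violation, on more than 32 edges, or on
an edge touching more than two vertices — the rare pathological
partitions.  Events are assigned to clusters by nearest grid node, with
boundary nodes resolved to the lowest-numbered adjacent cluster.

## Dip significance (edge pruning)

With density f̂ = scale · (K ∗ w), independent events give the pointwise
variance estimate Var f̂ ≈ scale² · (K² ∗ w), computed by a second DCT
pass with the squared kernel taps.  An edge is significant when **both**
modes it separates exceed its saddle by z_α standard errors,
SE² = Var f̂(mode) + Var f̂(saddle), one-sided α = 0.05 Bonferroni-corrected
by the current edge count.  Edges are tested in descending saddle order;
the first insignificant edge is removed, its faces merged (the merged
face keeps the higher mode and the union of member clusters; edges now
parallel at a degree-2 vertex are spliced into one chain) and the scan
restarts, terminating when all surviving edges are significant.  The test
statistic of the merging literature is not printed in full anywhere we
could adopt it from, so this z-type formulation — matching the verbal
description and the two-DCT computation — is this package's own choice,
with α exposed as configuration.  Its empirical behaviour is pinned by the
test suite: the variance estimate tracks replicate-to-replicate KDE
variance, single-Gaussian nulls stay unsplit in ≥ 90% of runs, and
8-kernel-width separations are detected essentially always.

## Candidate enumeration

A usable gate boundary is a subset of edges forming one continuous curve
(the grid border closes curves terminating on it) and splitting the faces
into two contiguous groups.  These are enumerated on the dual graph (node
per face, dual edge per cluster edge) with faces and edges as bit vectors:
removing a dual edge merges its endpoint nodes; dual edges that then join
the same node pair merge by OR-ing their masks (the spliced cluster
edges); dual edges collapsing to self-loops are dropped.  A depth-first
stack search explores removal sequences whose units come in strictly
increasing order of their lowest original-edge bit; every simplified dual
with exactly one edge yields a candidate (its composite mask and the two
merged node sets).  The low-bit unit ordering makes every reachable
simplified dual reachable by exactly one canonical path, so the search is
complete without factorial duplication and the emitted set is invariant
under edge relabelling.  Candidates are deduplicated defensively and
re-verified geometrically on emission (contiguity of both sides, cut =
all edges between the sides, curve continuity); the whole stage is tested
for exact agreement with a brute-force partition search on random Voronoi
fixtures of up to 6 faces.

## Scoring, selection, recursion

Raw score: n · Σ over boundary grid points of density · (2W/256) — the
estimated event count in a ±W strip around the cut.  The absolute scale is
approximate by construction; only the ordering is contractual.  In
`best_balance` mode (default, and used for all the package's own results)
the raw score is divided by the balance factor 4P(1−P), P being the event
fraction on the side containing the lowest-numbered face; degenerate
splits (P ∈ {0, 1}) are discarded.  The candidate with the smallest
adjusted score across all pairs wins, ties broken by (pair indices, edge
mask).  Raw strip scores are compared across pairs without per-pair
renormalisation.

Events follow their cluster's side of the winning boundary (cluster
membership, not point-in-polygon against the simplified reporting
polygon, defines children).  Recursion is depth-first, lower-weight child
first (affects only leaf numbering); it stops when no candidate survives,
or when the population falls below the optional absolute/relative
minimum sizes (off by default) or below 50 events.  Every algorithmic
dead end is a leaf, never an error.

## Outputs

The gating tree is JSON-encoded: per split node the dimension pair, raw
and adjusted boundary scores, P, final kernel sd and widening passes; per
child its gate polygon — the side's grid-region outline, closed along the
border where needed, simplified by Ramer–Douglas–Peucker (shapely) at 1%
of full scale — and a heuristic ± label per phenotyping dimension from
leaf-vs-parent medians (display only, non-normative).  The per-event CSV
carries the leaf id and the Mahalanobis distance from the leaf centre over
the phenotyping dimensions (covariance ridge-regularised by 1e−6 × trace
when singular).  Both files are byte-stable across reruns.

Comparison utilities: shared-event match tables, Jaccard similarity
|A∩B|/|A∪B|, and Central Similarity — Jaccard after restricting A∪B to
its central 80% by Mahalanobis distance from the A∪B mean.  The joint
A∪B reading keeps the coefficient symmetric in its arguments.

## Synthetic data

`synth.generate_mixture` draws seeded Gaussian mixtures on the unit cube
with exact ground-truth labels; out-of-cube draws are **resampled**, not
clipped, since clipping creates wall spikes the clustering would
legitimately detect, confounding null tests.  Mass-mode fixtures replace
declared negative dimensions with zero-inflated exponentials
(zero fraction 0.4).  Standard fixtures: a 50/50 two-component mixture in
2-D (means 0.3/0.7 per axis, sd 0.03 — ≥ 8 initial kernel widths apart)
and an equal-weight five-component mixture in 3-D whose first projection
separates all pairs by ≥ 0.30.  `generate_planar_partition` builds random
Voronoi tessellations of the grid (2–6 faces) as cluster-graph fixtures.

What the generator does **not** emulate: spillover/compensation artifacts,
acquisition drift, doublets, heavy-tailed or skewed populations, and
overlapping populations with shoulder (non-modal) structure.  Passing
tests therefore demonstrate correctness of the machinery and its
statistical calibration under the stated data model, not robustness to
every real-data pathology.

## Problem sizes and numerical choices

The verification suite runs the full engine at n = 50,000 events per
replicate for mixture recovery (100 replicates per mixture), n = 20,000
for null control and qualification calibration, 200 random partitions for
the enumeration oracle, and 20 weight arrays × 3 bandwidths for the KDE
oracle; the standalone acceptance script uses 25–50 replicates per
quantity.  These sizes give the Monte-Carlo rates ±~2–4% resolution while
keeping a full verification run in a few minutes on one core.

Tie-breaks are fixed everywhere (row-major grid order, lowest cluster id,
lexicographic candidate order) so the pipeline is deterministic by
construction.  DCT round-off can produce −1e−18-scale densities; they are
clipped to zero.  Degenerate inputs — zero-variance dimensions, empty
windows, single-cluster pairs, sub-50-event populations — all resolve to
"no split here" rather than errors.

## Known limitations

- The dip-test calibration constants are this package's own; bit-level
  agreement with other implementations of density-based merging is not a
  goal.
- Edge masks are capped at 32 bits; denser partitions rely on kernel
  widening upstream (graphs needing more edges with ≤ 12 clusters are
  extremely rare).
- Grid size is fixed at 257 × 257 and bandwidths are global, not
  adaptive.
- The heuristic leaf labels are naïve median ± calls and must not be read
  as biological assessments.
- Execution is single-threaded; the work units (pair analyses) are
  independent by construction, so parallel scheduling would not change
  results, but none is implemented.
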