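# epp-gate — exhaustive projection pursuit for cytometry

Automated, data-driven gating for flow and mass cytometry.  Given a
compensated, pre-gated event table, the engine repeatedly finds the
statistically best two-part split of the current cell population across all
informative 2-D marker projections and recurses until no statistically
supported split remains.  The terminal populations — *algorithmic
phenotypes* — are emitted as a conventional gating tree (JSON, with gate
polygons and boundary scores) plus a per-event CSV, so results drop into
the same review workflow as manual gating.  It is aimed at cytometrists and
computational biologists who want reproducible, assumption-light population
discovery that still looks like gating.

## The algorithm

For each population, in order:

1. **Qualification.** Each phenotyping dimension is scored by the
   Kullback–Leibler divergence of its marginal from a moment-matched normal
   (and, in mass-cytometry mode, of its non-zero values from a
   moment-matched exponential).  Dimensions that look like a uniform
   positive or negative stain (KLD below 0.04, exponential below 0.2) are
   omitted; all pairs of surviving dimensions are examined.  If fewer than
   two survive, the most divergent pair is tried anyway.
2. **Density estimation.** Events are linear-binned onto a 257 × 257 grid
   and smoothed with a Gaussian kernel (initial σ = W = 0.01 of full scale;
   0.025 recommended for mass data) computed exactly via the type-I DCT
   with reflective boundaries.
3. **Modal clustering.** Grid points are classified in descending density
   order: an unattached point founds a cluster (a mode), a point between
   two clusters becomes a boundary point.  New modes must clear a
   counting-noise floor: a kernel-spot-sized window of grid points must
   hold more than σ² = 9 events.  The labelled grid condenses into a planar
   *cluster graph* — faces (clusters), edges (boundary chains), vertices
   (≥ 3-cluster meeting points).  Partitions with more than 12 clusters or
   32 edges widen the kernel by √2 and restart.
4. **Dip significance.** Each edge's saddle (its highest-density point)
   is tested against both adjacent modes with a one-sided z test using the
   squared-kernel variance estimate of the KDE (α = 0.05, Bonferroni over
   edges).  Edges without a significant dip are removed and their clusters
   merged.
5. **Candidate enumeration.** Every subset of edges forming one continuous
   curve that divides the faces into two contiguous groups is enumerated by
   systematic simplification of the dual graph with bit-vector arithmetic.
6. **Scoring and recursion.** A candidate's raw score is the estimated
   event count within ±W of its boundary (misallocation scales with events
   near the cut, so smaller is better).  In `best_balance` mode (default)
   the score is divided by 4P(1−P), P the event fraction on one side.  The
   globally best split divides the population; both children re-enter
   step 1.

The engine is fully deterministic: identical input and configuration give
byte-identical outputs.

## Worked example

```bash
# simulate a fluorescence-like 60/40 two-population sample
epp simulate --spec spec.yaml --out events.csv
# wrote 20000 events to events.csv

epp run --input events.csv --config cfg.yaml --out out/
# read 20000 events (0 censored)
# 2 phenotypes -> out/gating_tree.json, out/events.csv
```

with `spec.yaml` declaring a mixture of two Gaussian components at
(0.30, 0.35) and (0.70, 0.65) (sd 0.03, weights 0.6/0.4) and `cfg.yaml`
declaring both columns as already-transformed phenotyping dimensions.
The resulting tree:

```
n_leaves: 2
root split: ['M1', 'M2']  boundary_score: 0.0  P: 0.6025  kernel_sd: 0.01
child: 7951 events,  label M1+M2+, polygon 7 vertices
child: 12049 events, label M1-M2-, polygon 7 vertices
```

Read: the root population split on the (M1, M2) projection along a
boundary with essentially zero events within ±W of it (`boundary_score`
≈ 0 — a clean valley), putting 60.25% of events on one side (`P`), close
to the true 60/40 mixing weights; each child's gate polygon is simplified
to 7 vertices at the default 1% tolerance.  `out/events.csv` holds one row
per event with its leaf id and the Mahalanobis distance from the leaf
centre:

```
event_index,cluster_id,mahalanobis
0,1,1.655827782
1,1,1.818043008
```

## Configuration surface

All working parameters are exposed (`RunConfig`, `ClusterConfig`,
`QualificationConfig`, `DbmConfig` or the YAML config for the CLI):
KLD thresholds (0.04 / 0.2), initial kernel width (0.01 / 0.025), noise
floor σ (3), cluster cap (12), edge cap (32), widening cap (8), dip-test α
(0.05) and correction, selection mode, minimum population sizes, and the
polygon simplification tolerance (1%).  See `docs/methods.md` for what
each does and why the defaults are what they are.
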