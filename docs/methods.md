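# Methods

## Clustering space

Fluorescence intensities span several decades, and Euclidean distance on
raw intensities would be dominated by the brightest channels.  Events are
therefore transformed per channel as `asinh(x / cofactor)` — near-linear
around zero, logarithmic for bright signal — and then linearly rescaled so
each channel's observed range maps onto [0, 100].  With that convention a
distance grid in unit increments resolves roughly percent-of-range steps,
and the default grid (d = 1..50, step 1) spans from well below
within-population spread to half the total range.  The cofactor default of
150 suits typical conventional-flow PMT scales and is configurable; both
the compression and the rescale are strictly monotone per channel, and raw
intensities are retained alongside so MFI reporting is never affected by
the transform.  The transform choice is deliberately declarative
(`TransformSpec`): clustering on raw or differently scaled data is a
configuration, not a code change.

## The sweep

The engine maintains one invariant set of labels over the discovery
events: 0 = unattributed, 1..K in order of cluster creation.  At each grid
level d, growth precedes discovery:

* **Growth** is iterated synchronously to a fixed point: in each round,
  every unattributed event whose nearest attributed event lies within d
  joins that event's cluster.  Ties on exact distance go to the lower
  cluster id (resolved across the 4 nearest neighbours, which covers any
  realistic tie multiplicity).  Growing first biases boundary events
  toward older clusters — the ones born at higher density — and a chain of
  events can be absorbed within a single level.
* **Discovery** partitions the remaining unattributed events into
  connected components of the ≤ d distance graph (kd-tree pair
  enumeration + union-find); components with ≥ `nmin` members become new
  clusters, numbered after all existing ones, in order of decreasing size
  (ties: smallest contained row index).

Consequences worth stating explicitly: clusters never merge (an
ε-component touching two clusters is split by the nearest-attributed-event
rule during growth), a non-zero label never changes, coverage is
non-decreasing in d, and every cluster has at least `nmin` members at its
creation distance.  The distance comparison is ≤ d; with a dense grid the
difference from a strict inequality affects only measure-zero ties, but the
convention matters for bit-exact reproducibility.  The sweep stops after
the first level whose coverage reaches the target (default 0.95), else at
grid end; discovery-set leftovers stay in cluster 0.

Nearest-neighbour work uses exact kd-trees with an incrementally
maintained nearest-attributed-distance cache, so each growth round costs
one tree build over the newly attributed batch plus one query per
remaining event.  Correctness is defined by a brute-force O(n²) union-find
oracle in the test suite; the spatial index is purely an efficiency
choice.

## Subsampling and attribution

Discovery uses a constant number of events per sample (default 25 000,
`min(quota, sample size)` for small samples) drawn uniformly without
replacement so each sample contributes equally to cluster discovery.
Subsampling is the only stochastic step; the seed is a mandatory config
field.  Events are processed in canonical (sample_id, event_index) order,
making results invariant under permutation of input rows.

Held-out events are attributed to the closest cluster — by centroid
(arithmetic mean in clustering space, O(K) per event; default) or by
nearest attributed discovery event (`nearest_event`, the higher-fidelity
option).  Held-out events are always attributed unless
`max_attribution_distance` is set, in which case distant events fall back
to cluster 0.  Because the coverage rule keeps sweeping until 95% of
discovery events are attributed, diffuse background events near population
clusters are absorbed by design; population fractions computed from
cluster labels therefore run slightly above the gated reference fractions,
which is inherent to the method, not an artifact of this implementation.

## Annotation

Two assignment modes are provided because they fail differently:

* `label_vote` (default when per-event manual labels exist): winning
  population = modal manual label among the cluster's discovery events;
  assigned iff the winner is a real gate (not the reserved "ungated"
  label) and its share — the reported purity — reaches the threshold
  (default 0.5).  Auditable, and yields an explicit "unassigned" category.
* `mfi_nearest`: per-channel z-scoring of cluster and reference MFI
  profiles with pooled statistics, assignment to the nearest profile by
  Euclidean distance.  Never unassigned; useful when only population-level
  summaries of the manual gating exist.

On cleanly separable data the two agree (tested); MFI is always the
arithmetic mean of raw intensities.

## Unimodality quality control

A cluster that straddles two populations shows a bimodal marker
distribution.  Each cluster is screened per channel with Hartigan's dip
statistic — the sup-norm distance between the empirical CDF and the
nearest unimodal CDF — computed by the iterative convex-minorant /
concave-majorant narrowing scheme.  The implementation is pinned down in
the tests against a linear-programming oracle that minimises the
sup-distance over all piecewise-linear unimodal CDFs (including an atom at
the mode) on hundreds of random small samples, exactly.

P-values compare against the dip distribution of uniform samples of equal
size — the standard reference null, conservative for lighter-tailed
unimodal shapes such as Gaussians.  The default source is a bundled
quantile table simulated at 5 000 replicates per size over a grid of 22
sizes (8 to 50 000), interpolated in log n on the `dip·sqrt(n)` scale; the
table's tail resolution floors reported p-values at 5·10⁻⁴.  A direct
Monte-Carlo option (`method="montecarlo"`) is available when exact
tail behaviour matters.  A cluster is good quality iff no channel rejects
at α = 0.05 with Bonferroni correction across the panel's channels —
conservative, so the realised false-alarm rate on clean clusters sits
below α.  Clusters under 8 events cannot be tested and auto-pass with a
flag.  All-equal samples get dip 0, p 1 by convention.

## Frequencies

The frequency matrix reports, per sample, the fraction of events in each
cluster, with cluster 0 in the denominator so entries read as "fraction of
all analysed events".  Grouping by an assignment pools clusters into their
populations, keeps "unassigned" as a row and cluster 0 as its own
`cluster_0` row — column sums are exactly invariant under grouping, and
counts always total the per-sample event counts.

## Synthetic cohorts

The generator emulates a 10-channel PBMC immunophenotyping panel.  Ten
named populations carry the reference proportions of a manually gated
cohort (CD4+ 0.410, classical monocytes 0.087, CD8+ 0.081, CD56dim NK
0.049, B cells 0.047, non-classical monocytes 0.005, intermediate
monocytes 0.004, pDC 0.003, CD56bright NK 0.003, mDC 0.001; total 0.690),
and the remaining 0.310 is a diffuse "ungated" background.  Marker means
follow the gating phenotype logic (four levels — negative 80, dim 1 500,
positive 8 000, bright 25 000 arbitrary units, with proportionate spreads)
so that every pair of named populations differs strongly in at least one
channel, as the corresponding real populations do.  Events are
truncated-at-zero Gaussians per channel times a per-event lognormal factor
(σ = 0.2) mimicking staining/cell-size variation; per-sample abundances
are Dirichlet-jittered (concentration 2 000, about a percentage point of
spread on the CD4+ fraction); per-sample totals vary uniformly within a
configured range.  The background is a wide truncated Gaussian
(mean 600, sd 3 000) per channel, diffuse enough that the cluster-0 and
"unassigned" code paths are genuinely exercised.

What the generator does **not** emulate: spillover/compensation error,
autofluorescence, batch and instrument drift, doublets, or correlated
marker noise within a population.  Tests passing on these fixtures
demonstrate the algorithmic contracts (density semantics, recovery of
well-separated populations at realistic abundances including rare ones,
calibration of the dip screen) — not robustness to those instrumental
effects.

## Problem sizes used in the validation runs

The cohort-scale checks run 20 samples of 30 000–60 000 events
(~0.9 M events) with discovery at 5 000 events/sample (100 000 points,
10-D) and nmin 20 vs 60; the held-out check uses 6 samples of
15 000–25 000 events with half of all events excluded from discovery; the
brute-force sweep cross-check uses up to 500 points in up to 10
dimensions.  These sizes make the full suite run in a few minutes on one
CPU while keeping every population, including mDC at 0.1%, above the
density gate.

## Known limitations

* FCS support is deliberately minimal: list-mode float/integer data,
  `$PnE` decoding, both byte orders; spillover matrices are read but never
  applied, and pre-gating (debris/doublets/dead cells) is assumed done
  upstream — the loader only drops non-finite rows.
* Growth tie-breaking consults the 4 nearest attributed events; a >4-way
  exact distance tie could in principle miss the lowest cluster id.
* The epsilon-component step enumerates all ≤ d pairs; pathological inputs
  (a large point set at mutual distances ≈ d) can make that quadratic in
  memory.
* `nmin` is not selected automatically; the practical recommendation is to
  aim for roughly 50–100 clusters and regroup.
* t-SNE coordinates are deterministic per seed but not comparable across
  runs with different inputs.
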