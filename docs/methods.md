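# Methods

This note documents the models, conventions and numerical choices behind
`phylocarto`, and what the synthetic-data generator does and does not
emulate.

## Scenario extraction and depth gradients

The scenario is the preorder list of parent→child transitions; each path
carries the parent's and child's (lat, lon) and absolute times. Times are
decimal years anchored at the most recent sampling date when one is given;
otherwise they count back from 0 at the youngest tip. Path counts obey
|paths| = |nodes| − 1, specializing to 2n − 2 on bifurcating trees.

Depth gradients operate on **topological** depth: root-emanating paths get
the tree's maximum root-to-tip edge count and each child path gets its
parent path's depth minus one, floored at zero. A time-proportional variant
would be possible, but the unit-decrement rule is the documented behavior
and is what the implementation commits to. Numeric gradients evaluate to
`base + offset·depth` clamped at 0 (no negative thickness or opacity);
color gradients interpolate the two endpoint colors linearly in RGB with
fraction depth/max_depth — RGB because it is reproducible bit-exactly,
whereas perceptual spaces vary by library and white point. A zero
max_depth with an active color gradient returns the first endpoint.

## Clustering conventions

All clustering acts on **both** tip and internal-node localities, in raw
(lat, lon) degree space with the Euclidean metric. This is deliberate and
matches the interactive-method semantics the module reproduces; it is *not*
a great-circle clustering, and clusters near the poles or the antimeridian
are distorted accordingly. The migration module is the only place where
spherical geometry is used.

K-means is Lloyd's algorithm exactly: initial centroids drawn uniformly at
random inside the bounding box of the data (intersected with user bounds),
assignment by nearest centroid with ties to the lowest index, centroid
update by arithmetic mean, convergence when the assignment stops changing,
with a 1000-iteration cap against tie cycling. An emptied cluster is
re-seeded at the point farthest from its current centroid — a standard
Lloyd repair that keeps k clusters and preserves the non-increasing
objective. Runs are bit-reproducible given the seed (numpy PCG64).
When lat/lon bounds are supplied they act on both the seeds and the data:
localities outside the box are not force-assigned to a distorted cluster
but set aside in a residual cluster, which keeps the in-bounds clustering
interpretable.

Grid cells are half-open `[edge, next)` with the last cell closed, so
points on interior edges deterministically belong to the higher cell.
Polygon (lasso) selection is boundary-inclusive and first-polygon-wins;
self-intersecting polygons are rejected via shapely validity. Convex hulls
come from shapely and are normalized to counter-clockwise rings, with
degenerate outputs (1 vertex for coincident points, 2 for collinear) kept
as such rather than inflated.

## Transition trees, collapsing, compression

The transition tree contracts maximal *connected* same-cluster regions: a
cluster occurring in two parts of the phylogeny not linked by same-cluster
edges yields two summary nodes. This is what makes sibling collapsing
meaningful — merging sibling summary nodes of the same cluster (taxon
counts and member sets summed, repeated until fixed point) would be vacuous
if regions were pooled globally. Taxon counts always sum to n_tips, before
and after collapsing.

The compression statistic is reported as the **floor** of the percentage,
`⌊100·(1 − E/P)⌋`; flooring (rather than rounding) is the convention that
reproduces the reference value 81 for P = 206, E = 38 (the exact reduction
is 81.55 %).

Transition matrices count each path into `[cluster(parent)][cluster(child)]`;
the diagonal is intra-cluster mass and the directed total always equals the
path count. Symmetric mode folds i→j and j→i into both off-diagonal cells
and leaves the diagonal alone. Optional ordering sorts rows by centroid
latitude and columns by centroid longitude, ascending; empty clusters
(NaN centroids) sort last.

## Brush windows

Window membership is closed on both ends: a node exactly on a window edge
is inside the selection. Categories follow node membership — both nodes in
(complete), parent only (downstream partial, an outgoing migration), child
only (upstream partial, incoming), neither but the window inside the branch
(total partial, in transit), no overlap (excluded). The included fraction
is overlap length divided by branch duration, and clipped endpoints are
linear interpolations in (lat, lon) — consistent with the straight-segment
path geometry, not great-circle arcs.

Two consequences of the closed-interval choice are documented rather than
hidden. First, fractions over abutting windows [a,b], [b,c] add exactly to
the fraction over [a,c] for positive-duration branches (the shared instant
has zero measure); zero-length branches sitting exactly at b are counted by
both windows. Second, a branch that touches a window at a single instant
through one of its nodes is categorized by node membership with fraction 0
— the "partial implies positive fraction" rule holds everywhere except on
this measure-zero corner, where membership and proportionality genuinely
conflict and membership wins. Zero-length branches are complete when their
instant is inside and excluded otherwise.

Animation frames are `[t, t+width]` stepped by `step` (sliding) or the
gradual reveal `[t_min, t]` (cumulative, monotone in its set of complete
paths).

## Migration curves

Great-circle distances use the haversine formula on a sphere of radius
6371.0088 km (IUGG mean radius; the constant is pinned for
reproducibility). Haversine is used rather than the spherical law of
cosines for conditioning near zero, and rather than ellipsoidal formulas
because the quantity of interest is the great circle. Curves accumulate
(branch length, displacement) from the root, so both coordinates are
non-decreasing along every lineage and each increment equals the
single-branch displacement exactly. Rapid-migration flagging compares the
per-branch rate km/year to a threshold; a zero-duration branch with
non-zero displacement has infinite rate and is always flagged.

## Ancestral state reconstruction

The F81-like model is parameterized by stationary frequencies π and a
branch-scaling factor s, with β = 1/(1 − Σπ²) normalizing to one expected
substitution per unit of scaled length — without this normalization s and
the time scale would be confounded. Three π modes are provided: empirical
tip frequencies with a +1 pseudocount (default — "F81-like" implies
unequal frequencies and tip frequencies are the standard estimate), equal,
and user-supplied. Oracle comparisons in the test suite always fix π
explicitly so nothing depends on this choice.

The total likelihood uses Felsenstein pruning with per-node rescaling
(divide each internal partial vector by its maximum, accumulate the log
factors). Rescaling, rather than full log-space products, keeps the
exhaustive-enumeration comparisons at 1e-10 agreement. Marginal posteriors
come from the standard up-down pass; tip marginals are point masses (or
renormalized ambiguity sets). The joint reconstruction is the Pupko
max-product dynamic program with back-pointers; ties break to the lowest
state index for determinism. The joint log-likelihood never exceeds the
total log-likelihood (a max never beats a sum).

The scale is fitted by bounded Brent minimization of the negative
log-likelihood over log s in the bracket (1e-4, 1e3), xatol 1e-7, and the
returned optimum is additionally compared against both bracket ends so an
invariant character (whose likelihood increases monotonically as s → 0)
cleanly returns the lower bound.

Display retention keeps, per node, every state whose posterior reaches
`max · (1 − p/100)` (with a 1e-12 tolerance for float noise); the majority
modality is always retained. Pie counts tally retained categories per
cluster or per transition-tree node over **all** nodes by default, with a
tips-only flag, since every node of the phylogeny is analyzed.

## Synthetic data

The generator emulates the relevant features of a continuous
phylogeographic summary tree: an ultrametric Yule topology (default birth
rate 1/lineage/year, 50 tips — sizes of the same order as the viral
demonstration datasets the tool targets), independent Brownian motion of
latitude and longitude along branches (default σ = 1°/√year, a regional-
scale dispersal), and an F81 trait (3 equal-frequency states, true scale 1).
Brownian motion on raw degrees mirrors the planar bivariate diffusion used
by continuous trait models at regional scales and keeps the closed-form
variance checks exact; latitude clamping and longitude wrapping distort
only near the domain edges and are range-checked, not modeled. Not
emulated: relaxed random walks, rate heterogeneity, extinction, sampled
ancestors, location uncertainty (HPD rings are carried through I/O but not
generated). Passing tests therefore demonstrate correctness of the
computations on BEAST-like inputs, not robustness to model misspecification
in real analyses.

Each stochastic layer (topology, locations, trait) uses its own RNG stream
keyed by a crc32 of the layer name under the master seed, so layers are
independently reproducible and adding a layer never shifts another's draws.

## Problem sizes in the test and acceptance runs

Unit and property tests run on trees of 2–104 tips; the reconstruction
oracle sweep enumerates all internal assignments on 200 random cases with
≤5 tips and ≤3 states; scale recovery uses 20 replicates of 100 tips per
true scale in {0.25, 1, 4}; conservation checks run on 100 simulated
clustered instances of 10–24 tips. The acceptance script simulates one
104-tip tree. The whole suite completes in well under a minute.

## Known limitations

- Euclidean-degree clustering is faithful to the method it reproduces but
  geographically distorted at high latitudes and across the antimeridian.
- Transition paths and clipped segments are straight in (lat, lon); only
  scalar distances are great-circle.
- The NEXUS writer emits the paired-key dialect (`location1`/`location2`);
  vector-key input is read but not re-emitted in vector form.
- The ASR module covers the F81-like family only (no GTR, no asymmetric
  rates, no among-branch rate variation) and a single character at a time.
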