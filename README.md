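# phylocarto

Phylogeographic scenarios from location-annotated time trees.

Continuous phylogeographic inference (BEAST + TreeAnnotator) produces a
time-calibrated summary tree whose every node — sampled tip or inferred
ancestor — carries latitude/longitude coordinates. Reading such a tree
recursively from the root to its leaves turns every parent→child edge into
a dispersal *transition*; the complete set of transitions is the
*phylogeographic scenario*. For a fully bifurcating tree with *n* tips the
scenario has exactly 2*n* − 2 paths, which quickly becomes unreadable for
real epidemics. `phylocarto` is a headless library + CLI for researchers in
molecular epidemiology and phylogeography that computes everything needed
to explore and summarize such scenarios:

- **treeio** — read/write TreeAnnotator-dialect annotated NEXUS
  (`[&location1=…,location2=…]` comments, vector keys, HPD rings, translate
  tables), with key autodetection and absolute node times in decimal years;
- **scenario** — transition-path extraction, topological depth gradients
  for the four graphical variables (thickness, curvature, opacity, color),
  upstream/downstream highlight sets, GeoJSON export;
- **cluster** — spatial clustering of *all* localities (tips and
  ancestors): Lloyd's K-means in lat/lon degree space with uniform-random
  initialization inside the data's bounding box, anchor nearest-centroid
  assignment, rectangular grids, lasso polygons, clade selection; minimum
  convex hulls;
- **summary** — the multifurcating inter-cluster *transition tree* obtained
  by contracting connected same-cluster regions, sibling collapsing, the
  floored compression percentage, and directed/symmetric k×k transition
  matrices (exchange maps);
- **timeslice** — brush-window classification of each path as complete /
  total partial / upstream partial / downstream partial / excluded, with
  proportional clipped geometry, plus sliding or cumulative animation
  frames;
- **migration** — haversine great-circle displacement per branch (Earth
  radius 6371.0088 km), cumulative migration-distance curves, and rapid-
  migration flagging;
- **asr** — maximum-likelihood ancestral reconstruction of a discrete
  character under an F81-like model with an ML-fitted branch-scaling
  factor: pruning likelihood, marginal posteriors, joint (Pupko) states,
  and the majority-modality-minus-*p*% retention rule with per-cluster pie
  counts;
- **simulate** — Yule trees + Brownian lat/lon dispersal + F81 trait
  evolution written as annotated NEXUS, so the whole pipeline is testable
  with known ground truth and no downloads.

## The model at the core

A transition tree summarizes a scenario: with localities grouped into *k*
clusters, maximal connected same-cluster regions of the phylogeny contract
to single nodes and only inter-cluster edges remain. The reduction from the
original 2*n* − 2 paths to the *E* summary edges is reported as

    compression = ⌊100 · (1 − E / (2n − 2))⌋ per cent.

For the discrete-trait module, the character evolves by a continuous-time
Markov process whose substitutions land on state *j* with stationary
probability π*j*, giving

    P(j | i, t) = π_j + (δ_ij − π_j) · exp(−β · s · t),   β = 1 / (1 − Σ_k π_k²),

where *s* is a constant branch-length scaling factor fitted by maximizing
the Felsenstein pruning likelihood (Brent search on log *s*).

## Worked example

```sh
phylocarto simulate --n-tips 20 --sigma 1.5 --seed 11 --out-prefix demo
phylocarto run demo.nexus --k 3 --seed 5 --frames 4 --trait-key trait --out-dir out
```

The first command writes `demo.nexus` (annotated tree) plus ground-truth
CSVs. The second prints `out/manifest.json` and fills `out/` with the
scenario GeoJSON, cluster CSV + hull GeoJSON, transition tree
(Newick + GeoJSON), transition matrix CSV, migration-curve CSV, four
animation frames and the ASR table. Stepwise, the same analysis:

```sh
$ phylocarto scenario demo.nexus --out scenario.geojson
38 transition paths -> scenario.geojson
$ phylocarto cluster demo.nexus --method kmeans --k 3 --seed 5 --out-prefix demo
3 clusters -> demo.clusters.csv
$ phylocarto summarize demo.nexus --clusters-csv demo.clusters.csv --out-prefix demo
38 transitions -> 4 inter-cluster transitions (compression 89%)
$ phylocarto asr demo.nexus --trait-key trait --out asr.csv
scale=1.30232655 logL=-19.036397 -> asr.csv
```

The 20-tip tree yields 2·20 − 2 = 38 transition paths; grouping its 39
node localities into 3 spatial clusters leaves 4 inter-cluster
transitions, an 89 % graphical compression. The ASR line reports the ML
branch-scaling factor of the trait and the data log-likelihood at that
scale; `asr.csv` holds per-node posterior probabilities, the joint ML
state, and the retained modality set used for pie charts.

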