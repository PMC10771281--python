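"""Synthetic continuous-phylogeography datasets with known ground truth.

The generator produces the kind of input a Bayesian phylogeographic
analysis would normally supply: a time-calibrated tree (pure-birth / Yule),
per-node latitude/longitude coordinates from independent Brownian motion
along branches, and a discrete trait evolved under an F81-like model —
written out as a TreeAnnotator-style annotated NEXUS file so every other
module can be exercised without any external download.

Each stochastic layer (topology, locations, trait) draws from its own
named RNG stream derived from the master seed, so adding one layer never
perturbs the draws of another and a fixed seed reproduces the dataset
bit-for-bit.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field

import numpy as np

from .asr import F81Model, f81_matrix
from .errors import ParameterError
from .tree import AnnotatedTree, Node
from .treeio import write_annotated_nexus


@dataclass
class SimulationConfig:
    n_tips: int = 50
    birth_rate: float = 1.0  # Yule speciation rate, per lineage per year
    sigma: float = 1.0  # Brownian dispersal SD, degrees per sqrt(year), per coordinate
    root_location: tuple[float, float] = (0.0, 0.0)
    states: list[str] = field(default_factory=lambda: ["A", "B", "C"])
    pi: list[float] | None = None  # default: equal frequencies
    true_scale: float = 1.0
    most_recent_sampling_date: float | None = 2020.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ParameterError("need at least 2 tips")
        if self.birth_rate <= 0:
            raise ParameterError("birth rate must be positive")
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


def _stream(seed: int, purpose: str) -> np.random.Generator:
    # crc32 gives a stable, process-independent stream key per purpose
    key = zlib.crc32(purpose.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def simulate_yule_tree(config: SimulationConfig) -> AnnotatedTree:
    """Pure-birth tree with ``n_tips`` tips, ultrametric in time.

    Standard forward construction: start with two lineages at the root,
    wait an Exp(rate * n_extant) time, split a uniformly chosen extant
    lineage, until n_tips lineages exist; then extend all extant branches
    by one final waiting time so tips align at the sampling date.
    """
    rng = _stream(config.seed, "topology")
    nodes: dict[int, Node] = {0: Node(id=0)}
    # extant lineages as (node id, time its branch started)
    t = 0.0
    extant: list[int] = []
    start_time: dict[int, float] = {}
    for _ in range(2):
        nid = len(nodes)
        nodes[nid] = Node(id=nid, parent=0)
        nodes[0].children.append(nid)
        extant.append(nid)
        start_time[nid] = 0.0
    while len(extant) < config.n_tips:
        t += rng.exponential(1.0 / (config.birth_rate * len(extant)))
        k = int(rng.integers(len(extant)))
        parent = extant[k]
        nodes[parent].branch_length = t - start_time[parent]
        children = []
        for _ in range(2):
            nid = len(nodes)
            nodes[nid] = Node(id=nid, parent=parent)
            nodes[parent].children.append(nid)
            start_time[nid] = t
            children.append(nid)
        extant[k] = children[0]
        extant.append(children[1])
    t += rng.exponential(1.0 / (config.birth_rate * len(extant)))
    for nid in extant:
        nodes[nid].branch_length = t - start_time[nid]
    for k, nid in enumerate(sorted(i for i in nodes if nodes[i].is_leaf)):
        nodes[nid].taxon_label = f"taxon_{k + 1}"
    return AnnotatedTree(
        nodes, root_id=0, most_recent_sampling_date=config.most_recent_sampling_date
    )


def simulate_brownian_locations(
    tree: AnnotatedTree,
    sigma: float,
    root_location: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> AnnotatedTree:
    """Independent Brownian motion per coordinate along every branch.

    Each child's coordinate is its parent's plus a Normal(0, sigma^2 * bl)
    step.  Latitude is clamped to [-90, 90] and longitude wrapped to
    (-180, 180], which distorts the diffusion only at the domain edges.
    """
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    rng = _stream(seed, "locations")
    root = tree.root
    root.latitude, root.longitude = root_location
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            continue
        parent = tree.nodes[node.parent]
        sd = sigma * np.sqrt(node.branch_length or 0.0)
        dlat, dlon = rng.normal(0.0, 1.0, size=2) * sd
        node.latitude = float(np.clip(parent.latitude + dlat, -90.0, 90.0))
        lon = (parent.longitude + dlon) % 360.0
        node.longitude = float(lon - 360.0 if lon > 180.0 else lon)
    return tree


def simulate_discrete_trait(
    tree: AnnotatedTree, model: F81Model, seed: int = 0
) -> dict[int, str]:
    """Evolve a discrete character down the tree; returns node id -> state.

    The root draws from pi; each child draws from the F81 transition row of
    its parent's state over the (scaled) branch length.  Tip states are
    also written onto the tree's ``discrete_trait`` annotations.
    """
    rng = _stream(seed, "trait")
    states: dict[int, str] = {}
    idx: dict[int, int] = {}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            idx[nid] = int(rng.choice(model.m, p=model.pi))
        else:
            row = f81_matrix(model, node.branch_length or 0.0)[idx[node.parent]]
            idx[nid] = int(rng.choice(model.m, p=row))
        states[nid] = model.states[idx[nid]]
        node.discrete_trait = states[nid]
    return states


def simulate_dataset(config: SimulationConfig):
    """Full synthetic dataset: tree + locations + discrete trait.

    Returns (tree, true_node_states).  The tree is ready for
    :func:`phylocarto.treeio.write_annotated_nexus`.
    """
    tree = simulate_yule_tree(config)
    simulate_brownian_locations(tree, config.sigma, config.root_location, config.seed)
    pi = config.pi or [1.0 / len(config.states)] * len(config.states)
    model = F81Model(states=list(config.states), pi=np.asarray(pi, float),
                     scale=config.true_scale)
    states = simulate_discrete_trait(tree, model, config.seed)
    return tree, states


def write_dataset(config: SimulationConfig, out_prefix: str) -> dict[str, str]:
    """Write NEXUS + ground-truth CSVs; returns {artifact: path}."""
    tree, states = simulate_dataset(config)
    paths = {
        "nexus": f"{out_prefix}.nexus",
        "locations": f"{out_prefix}.locations.csv",
        "states": f"{out_prefix}.states.csv",
    }
    with open(paths["nexus"], "w") as fh:
        fh.write(write_annotated_nexus(tree))
    with open(paths["locations"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "taxon", "latitude", "longitude"])
        for nid in tree.preorder():
            nd = tree.nodes[nid]
            writer.writerow([nid, nd.taxon_label or "", repr(nd.latitude), repr(nd.longitude)])
    with open(paths["states"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "taxon", "state", "true_scale"])
        for nid in tree.preorder():
            nd = tree.nodes[nid]
            writer.writerow([nid, nd.taxon_label or "", states[nid], repr(config.true_scale)])
    return paths
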