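"""Cluster-level summaries of a phylogeographic scenario.

Revisiting the phylogeny with every node assigned to a spatial cluster
yields the inter-cluster *transition tree*: maximal connected same-cluster
regions of the phylogeny contract to single summary nodes, and the edges
left between regions are the inter-cluster transitions.  The transition
tree is generally multifurcating and can be simplified further by
collapsing sibling summary nodes of the same cluster.  The companion
*transition matrix* (exchange map) counts transitions between every ordered
or unordered pair of clusters, with intra-cluster transitions on the
diagonal.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .cluster import SpatialClustering, check_coverage
from .errors import ParameterError
from .scenario import TransitionPath
from .tree import AnnotatedTree


@dataclass
class SummaryNode:
    id: int
    cluster: int
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    member_node_ids: set[int] = field(default_factory=set)
    taxon_count: int = 0


@dataclass
class TransitionTree:
    """Multifurcating rooted tree of cluster regions.

    Invariants: no edge joins two summary nodes of the same cluster, and
    taxon counts over all summary nodes sum to the tip count of the source
    phylogeny.
    """

    nodes: dict[int, SummaryNode]
    root_id: int

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    def edges(self) -> list[tuple[int, int]]:
        """(parent cluster, child cluster) per summary edge, preorder."""
        out = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            for c in reversed(node.children):
                out.append((node.cluster, self.nodes[c].cluster))
                stack.append(c)
        return out

    def total_taxa(self) -> int:
        return sum(nd.taxon_count for nd in self.nodes.values())


def build_transition_tree(
    tree: AnnotatedTree, clustering: SpatialClustering | dict[int, int]
) -> TransitionTree:
    """Contract maximal connected same-cluster regions of the phylogeny.

    A cluster occurring in two parts of the tree not connected through
    same-cluster edges yields two distinct summary nodes.  Each summary
    node's taxon count is the number of tips it absorbed.
    """
    assignment = clustering.assignment if isinstance(clustering, SpatialClustering) else clustering
    check_coverage(assignment, tree)

    region_of: dict[int, int] = {}
    snodes: dict[int, SummaryNode] = {}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        cluster = assignment[nid]
        if node.parent is not None and assignment[node.parent] == cluster:
            region = region_of[node.parent]  # absorbed into the parent's region
        else:
            region = len(snodes)
            parent_region = region_of[node.parent] if node.parent is not None else None
            snodes[region] = SummaryNode(id=region, cluster=cluster, parent=parent_region)
            if parent_region is not None:
                snodes[parent_region].children.append(region)
        region_of[nid] = region
        snodes[region].member_node_ids.add(nid)
        if node.is_leaf:
            snodes[region].taxon_count += 1
    return TransitionTree(nodes=snodes, root_id=region_of[tree.root_id])


def collapse_transition_tree(ttree: TransitionTree) -> TransitionTree:
    """Merge sibling summary nodes that share a cluster, recursively.

    Taxon counts and member sets of merged siblings are summed; merging is
    repeated down the tree until no two siblings share a cluster (the
    result is a fixed point: collapsing twice changes nothing).
    """
    nodes = {
        nid: SummaryNode(
            id=nd.id, cluster=nd.cluster, parent=nd.parent,
            children=list(nd.children),
            member_node_ids=set(nd.member_node_ids),
            taxon_count=nd.taxon_count,
        )
        for nid, nd in ttree.nodes.items()
    }
    queue = [ttree.root_id]
    while queue:
        nid = queue.pop(0)
        node = nodes[nid]
        by_cluster: dict[int, int] = {}
        merged_children = []
        for cid in node.children:
            child = nodes[cid]
            if child.cluster in by_cluster:
                keeper = nodes[by_cluster[child.cluster]]
                keeper.taxon_count += child.taxon_count
                keeper.member_node_ids |= child.member_node_ids
                for g in child.children:
                    nodes[g].parent = keeper.id
                    keeper.children.append(g)
                del nodes[cid]
            else:
                by_cluster[child.cluster] = cid
                merged_children.append(cid)
        node.children = merged_children
        queue.extend(merged_children)
    return TransitionTree(nodes=nodes, root_id=ttree.root_id)


def compression_statistic(n_original_paths: int, n_summary_edges: int) -> int:
    """Graphical compression achieved by summarization, as a floored integer
    percentage: floor(100 * (1 - summary / original))."""
    if n_original_paths <= 0:
        raise ParameterError("n_original_paths must be positive")
    if not (0 <= n_summary_edges <= n_original_paths):
        raise ParameterError("n_summary_edges must lie in [0, n_original_paths]")
    return math.floor(100.0 * (1.0 - n_summary_edges / n_original_paths))


@dataclass
class TransitionMatrix:
    counts: np.ndarray  # k x k integer counts
    mode: str  # directed | symmetric
    row_order: list[int]  # cluster indices, row i of counts = cluster row_order[i]
    col_order: list[int]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def transition_matrix(
    paths: list[TransitionPath],
    clustering: SpatialClustering | dict[int, int],
    mode: str = "directed",
    order_by_centroids: bool = False,
) -> TransitionMatrix:
    """Count cluster-to-cluster transitions over the scenario's paths.

    The diagonal holds intra-cluster transitions.  ``symmetric`` mode folds
    each off-diagonal pair (i, j)/(j, i) into a shared count placed in both
    cells; the diagonal is unchanged.  With ``order_by_centroids`` rows are
    sorted ascending by centroid latitude and columns ascending by centroid
    longitude (requires a :class:`SpatialClustering`).
    """
    if mode not in ("directed", "symmetric"):
        raise ParameterError(f"unknown matrix mode {mode!r}")
    assignment = clustering.assignment if isinstance(clustering, SpatialClustering) else clustering
    k = (clustering.k if isinstance(clustering, SpatialClustering)
         else max(assignment.values()) + 1)
    counts = np.zeros((k, k), dtype=int)
    for p in paths:
        try:
            i, j = assignment[p.parent_id], assignment[p.child_id]
        except KeyError as exc:
            raise ParameterError(f"path endpoint {exc} not covered by the clustering") from exc
        counts[i, j] += 1
    if mode == "symmetric":
        off = counts - np.diag(np.diag(counts))
        folded = off + off.T
        counts = folded + np.diag(np.diag(counts))
    row_order = list(range(k))
    col_order = list(range(k))
    if order_by_centroids:
        if not isinstance(clustering, SpatialClustering):
            raise ParameterError("centroid ordering needs a SpatialClustering")
        lat = [c[0] for c in clustering.centroids]
        lon = [c[1] for c in clustering.centroids]
        row_order = sorted(range(k), key=lambda c: (math.inf if math.isnan(lat[c]) else lat[c]))
        col_order = sorted(range(k), key=lambda c: (math.inf if math.isnan(lon[c]) else lon[c]))
        counts = counts[np.ix_(row_order, col_order)]
    return TransitionMatrix(counts=counts, mode=mode, row_order=row_order, col_order=col_order)


# ---------------------------------------------------------------------------
# export


def transition_tree_newick(ttree: TransitionTree) -> str:
    """Newick with ``cluster:taxon_count`` node labels (quoted, since the
    colon is a Newick delimiter)."""

    def render(nid: int) -> str:
        node = ttree.nodes[nid]
        label = f"'{node.cluster}:{node.taxon_count}'"
        if not node.children:
            return label
        return "(" + ",".join(render(c) for c in node.children) + ")" + label

    return render(ttree.root_id) + ";"


def transition_tree_geojson(ttree: TransitionTree, clustering: SpatialClustering) -> dict:
    features = []
    for nid, node in ttree.nodes.items():
        lat, lon = clustering.centroids[node.cluster]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": {"summary_node": nid, "cluster": node.cluster,
                               "taxon_count": node.taxon_count},
            }
        )
        if node.parent is not None:
            plat, plon = clustering.centroids[ttree.nodes[node.parent].cluster]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString",
                                 "coordinates": [[plon, plat], [lon, lat]]},
                    "properties": {"from_cluster": ttree.nodes[node.parent].cluster,
                                   "to_cluster": node.cluster},
                }
            )
    return {"type": "FeatureCollection", "features": features}


def write_transition_tree_geojson(ttree, clustering, out_path) -> None:
    with open(out_path, "w") as fh:
        json.dump(transition_tree_geojson(ttree, clustering), fh, indent=1)


def matrix_to_csv(matrix: TransitionMatrix, out_path) -> None:
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + [str(c) for c in matrix.col_order])
        for i, row in enumerate(matrix.counts):
            writer.writerow([str(matrix.row_order[i])] + [int(v) for v in row])
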