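"""In-memory model of a location-annotated, time-calibrated phylogeny.

The tree is rooted; every node carries latitude/longitude coordinates
(inferred for ancestors, observed for tips) and may carry a discrete trait
value and highest-posterior-density (HPD) polygon rings.  Node heights are
measured in time units before the most recent tip; when a most recent
sampling date (decimal year) is known, heights convert to absolute times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import LookupError_, PhylocartoError

#: tolerance used when checking that time flows from root to tips
HEIGHT_TOLERANCE = 1e-6


@dataclass
class Node:
    """One node of an :class:`AnnotatedTree`.

    ``branch_length`` is ``None`` on the root and a non-negative duration
    (same units as node heights, conventionally years) elsewhere.
    ``hpd_polygons`` holds zero or more (lat, lon) vertex rings describing
    location uncertainty; they are carried through I/O but never required.
    ``extra`` preserves unrecognized annotation keys verbatim.
    """

    id: int
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    branch_length: float | None = None
    taxon_label: str | None = None
    latitude: float = float("nan")
    longitude: float = float("nan")
    discrete_trait: str | None = None
    hpd_polygons: list[list[tuple[float, float]]] = field(default_factory=list)
    extra: dict[str, str] = field(default_factory=dict)
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


class AnnotatedTree:
    """Rooted tree with per-node geographic annotations.

    Parameters
    ----------
    nodes:
        Mapping of node id to :class:`Node`.  Parent/child pointers must be
        consistent and describe a single rooted tree.
    root_id:
        Id of the unique root.
    most_recent_sampling_date:
        Decimal year of the youngest tip, or ``None`` if the tree is not
        calendar-calibrated.
    """

    def __init__(
        self,
        nodes: dict[int, Node],
        root_id: int,
        most_recent_sampling_date: float | None = None,
    ):
        self.nodes = nodes
        self.root_id = root_id
        self.most_recent_sampling_date = most_recent_sampling_date
        self._compute_heights()

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> Node:
        return self.nodes[self.root_id]

    def node(self, node_id: int) -> Node:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise LookupError_(f"no node with id {node_id!r}") from None

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_tips(self) -> int:
        return sum(1 for nd in self.nodes.values() if nd.is_leaf)

    def tips(self) -> list[Node]:
        return [self.nodes[i] for i in self.preorder() if self.nodes[i].is_leaf]

    def preorder(self) -> list[int]:
        """Node ids in preorder (parent before children, children in order)."""
        order: list[int] = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return order

    def postorder(self) -> list[int]:
        return list(reversed([*self._reverse_postorder()]))

    def _reverse_postorder(self):
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(self.nodes[nid].children)

    def ancestors(self, node_id: int) -> list[int]:
        """Ids on the path from ``node_id``'s parent up to (and incl.) the root."""
        self.node(node_id)
        out = []
        cur = self.nodes[node_id].parent
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def clade(self, node_id: int) -> list[int]:
        """Ids of all nodes in the clade rooted at ``node_id`` (inclusive), preorder."""
        self.node(node_id)
        order: list[int] = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return order

    def is_bifurcating(self) -> bool:
        return all(
            len(nd.children) in (0, 2) for nd in self.nodes.values()
        )

    # -- time --------------------------------------------------------------

    def _compute_heights(self) -> None:
        # depth = time elapsed from the root; height = youngest-tip depth - depth
        depth: dict[int, float] = {self.root_id: 0.0}
        for nid in self.preorder():
            nd = self.nodes[nid]
            if nd.parent is not None:
                bl = nd.branch_length or 0.0
                depth[nid] = depth[nd.parent] + bl
        max_tip_depth = max(
            (depth[i] for i, nd in self.nodes.items() if nd.is_leaf), default=0.0
        )
        for nid, nd in self.nodes.items():
            nd.height = max_tip_depth - depth[nid]

    def node_times(self) -> dict[int, float]:
        """Absolute time of every node in decimal years.

        With a most recent sampling date the youngest tip sits at that date;
        without one, times are heights negated (the youngest tip at 0, the
        root at minus its height).
        """
        origin = self.most_recent_sampling_date or 0.0
        return {nid: origin - nd.height for nid, nd in self.nodes.items()}

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`PhylocartoError` on failure."""
        import math

        roots = [i for i, nd in self.nodes.items() if nd.parent is None]
        if roots != [self.root_id]:
            raise PhylocartoError(f"expected a single root {self.root_id}, found {roots}")
        for nid, nd in self.nodes.items():
            for c in nd.children:
                if self.nodes[c].parent != nid:
                    raise PhylocartoError(f"parent/child mismatch at nodes {nid}/{c}")
            if nd.parent is not None:
                if nd.branch_length is None or nd.branch_length < 0:
                    raise PhylocartoError(f"node {nid} has invalid branch length")
                if self.nodes[nd.parent].height <= nd.height - HEIGHT_TOLERANCE:
                    raise PhylocartoError(
                        f"height of node {nid} exceeds its parent's (time must flow root to tips)"
                    )
            if not (math.isfinite(nd.latitude) and math.isfinite(nd.longitude)):
                raise PhylocartoError(f"node {nid} has non-finite coordinates")
        if len(self.preorder()) != len(self.nodes):
            raise PhylocartoError("tree is not connected")
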