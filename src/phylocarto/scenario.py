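"""Phylogeographic scenario: the full set of parent-to-child transition paths.

Reading the annotated tree recursively from the root to its leaves, every
edge becomes a transition path from the parent's coordinates to the child's.
For a fully bifurcating tree with n tips there are exactly 2n - 2 such
paths.  Paths carry a topological depth used to drive depth gradients on
the four graphical variables (thickness, curvature, opacity, color):
root-emanating paths get the tree's maximum depth and the value decreases
by one per recursive step, floored at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import ParameterError
from .tree import AnnotatedTree

PATH_CATEGORIES = (
    "complete",
    "total_partial",
    "upstream_partial",
    "downstream_partial",
    "excluded",
)


@dataclass
class TransitionPath:
    """One dispersal transition along a tree edge."""

    parent_id: int
    child_id: int
    origin: tuple[float, float]  # (lat, lon) of the parent
    destination: tuple[float, float]  # (lat, lon) of the child
    start_time: float
    end_time: float
    depth: int = 0
    great_circle_km: float | None = None
    category: str = "complete"


@dataclass
class GradientSpec:
    """Depth gradient for one graphical variable.

    Inactive specs evaluate to ``base_value`` everywhere.  Active numeric
    gradients evaluate to ``base_value + offset * depth`` (floored at 0);
    an active color gradient interpolates linearly in RGB between the two
    endpoint colors with fraction depth / max_depth.
    """

    variable: str  # thickness | curvature | opacity | color
    active: bool = False
    base_value: float = 1.0
    offset: float = 0.0
    color_endpoints: tuple[tuple[int, int, int], tuple[int, int, int]] = field(
        default=((0, 0, 0), (255, 255, 255))
    )

    def __post_init__(self):
        if self.variable not in ("thickness", "curvature", "opacity", "color"):
            raise ParameterError(f"unknown graphical variable {self.variable!r}")


def extract_scenario(tree: AnnotatedTree) -> list[TransitionPath]:
    """One :class:`TransitionPath` per non-root node, in preorder, with depths."""
    times = tree.node_times()
    paths = []
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            continue
        parent = tree.nodes[node.parent]
        paths.append(
            TransitionPath(
                parent_id=parent.id,
                child_id=nid,
                origin=(parent.latitude, parent.longitude),
                destination=(node.latitude, node.longitude),
                start_time=times[parent.id],
                end_time=times[nid],
            )
        )
    return assign_depths(paths, tree)


def max_topological_depth(tree: AnnotatedTree) -> int:
    """Maximum number of edges on any root-to-tip path."""
    depth = {tree.root_id: 0}
    best = 0
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is not None:
            depth[nid] = depth[node.parent] + 1
            best = max(best, depth[nid])
    return best


def assign_depths(paths: list[TransitionPath], tree: AnnotatedTree) -> list[TransitionPath]:
    """Fill gradient depths: root paths get the tree's maximum topological
    depth; each child path gets its parent path's depth minus one, floored
    at zero."""
    max_depth = max_topological_depth(tree)
    by_child = {p.child_id: p for p in paths}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            continue
        path = by_child[nid]
        if node.parent == tree.root_id:
            path.depth = max_depth
        else:
            path.depth = max(by_child[node.parent].depth - 1, 0)
    return paths


def evaluate_gradient(spec: GradientSpec, depth: int, max_depth: int):
    """Value of a graphical variable at a given transition depth.

    Numeric variables return a float (never negative); ``color`` returns an
    (r, g, b) integer triple.
    """
    if not (0 <= depth <= max_depth) and max_depth > 0:
        raise ParameterError(f"depth {depth} outside [0, {max_depth}]")
    if spec.variable == "color":
        lo, hi = spec.color_endpoints
        if not spec.active or max_depth == 0:
            return lo
        f = depth / max_depth
        return tuple(round(a + (b - a) * f) for a, b in zip(lo, hi))
    if not spec.active:
        return spec.base_value
    return max(spec.base_value + spec.offset * depth, 0.0)


def upstream_downstream_sets(
    tree: AnnotatedTree, focal_node: int
) -> tuple[set[int], set[int]]:
    """Path ids (child ids) upstream (root-to-focal) and downstream (inside
    the focal clade) of a node; the two sets are disjoint."""
    tree.node(focal_node)
    upstream = {focal_node} | set(tree.ancestors(focal_node))
    upstream.discard(tree.root_id)
    if focal_node == tree.root_id:
        upstream = set()
    downstream = set(tree.clade(focal_node)) - {focal_node}
    return upstream, downstream


# ---------------------------------------------------------------------------
# export


def _hex(color: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*color)


def scenario_geojson(
    paths: list[TransitionPath],
    gradients: dict[str, GradientSpec] | None = None,
    max_depth: int | None = None,
) -> dict:
    """GeoJSON FeatureCollection of LineString features, one per path.

    Coordinates follow the GeoJSON convention (longitude first).  When
    gradient specs are given, evaluated thickness / opacity / curvature /
    color are attached as properties.
    """
    gradients = gradients or {}
    if max_depth is None:
        max_depth = max((p.depth for p in paths), default=0)
    features = []
    for p in paths:
        props = {
            "parent": p.parent_id,
            "child": p.child_id,
            "depth": p.depth,
            "start_time": p.start_time,
            "end_time": p.end_time,
            "category": p.category,
        }
        for name, spec in gradients.items():
            value = evaluate_gradient(spec, p.depth, max_depth)
            props[name] = _hex(value) if spec.variable == "color" else value
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [p.origin[1], p.origin[0]],
                        [p.destination[1], p.destination[0]],
                    ],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_scenario_geojson(paths, out_path, **kwargs) -> None:
    with open(out_path, "w") as fh:
        json.dump(scenario_geojson(paths, **kwargs), fh, indent=1)
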