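"""Migration distance over time.

For every parent/child node pair a point is computed whose abscissa is the
cumulative branch length from the root and whose ordinate is the cumulative
great-circle distance from the root; connecting each child's point to its
parent's turns the phylogeny into a bundle of migration curves that keeps
the tree topology while exposing slow and fast migrations as shallow and
steep segments.

Great-circle distances use the haversine formula on a sphere with the IUGG
mean Earth radius, 6371.0088 km.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

from .scenario import TransitionPath
from .tree import AnnotatedTree

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between two (lat, lon) points."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class CurvePoint:
    node_id: int
    parent_id: int | None
    cum_branch_length: float  # time units from the root
    cum_distance_km: float  # great-circle km accumulated from the root


@dataclass
class MigrationCurve:
    """Per-node cumulative (time, distance) points; the parent pointers
    reproduce the tree topology so the points form a curve bundle."""

    points: dict[int, CurvePoint]
    root_id: int


def migration_curves(tree: AnnotatedTree) -> MigrationCurve:
    """Preorder accumulation of branch lengths and great-circle displacements.

    The root sits at (0, 0); along every root-to-tip lineage both
    coordinates are non-decreasing.
    """
    points: dict[int, CurvePoint] = {}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            points[nid] = CurvePoint(nid, None, 0.0, 0.0)
            continue
        parent_pt = points[node.parent]
        parent_node = tree.nodes[node.parent]
        step = great_circle_km(
            (parent_node.latitude, parent_node.longitude),
            (node.latitude, node.longitude),
        )
        points[nid] = CurvePoint(
            nid,
            node.parent,
            parent_pt.cum_branch_length + (node.branch_length or 0.0),
            parent_pt.cum_distance_km + step,
        )
    return MigrationCurve(points=points, root_id=tree.root_id)


def fill_great_circle(paths: list[TransitionPath]) -> list[TransitionPath]:
    """Fill each path's ``great_circle_km`` field in place."""
    for p in paths:
        p.great_circle_km = great_circle_km(p.origin, p.destination)
    return paths


def flag_rapid_migrations(
    curves: MigrationCurve,
    paths: list[TransitionPath],
    rate_threshold_km_per_year: float,
) -> list[int]:
    """Child ids of paths whose dispersal rate exceeds the threshold.

    The rate is the branch's great-circle displacement divided by its
    duration; a zero-length branch with non-zero displacement is an
    instantaneous jump and is always flagged.
    """
    if rate_threshold_km_per_year <= 0:
        raise ValueError("rate threshold must be positive")
    flagged = []
    for p in paths:
        km = p.great_circle_km
        if km is None:
            km = great_circle_km(p.origin, p.destination)
        duration = p.end_time - p.start_time
        if duration <= 0:
            if km > 0:
                flagged.append(p.child_id)
            continue
        if km / duration > rate_threshold_km_per_year:
            flagged.append(p.child_id)
    return flagged


def curves_to_csv(curves: MigrationCurve, out_path) -> None:
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "parent_id", "cum_branch_length", "cum_distance_km"])
        for pt in curves.points.values():
            writer.writerow(
                [pt.node_id, "" if pt.parent_id is None else pt.parent_id,
                 repr(pt.cum_branch_length), repr(pt.cum_distance_km)]
            )


def plot_curves(curves: MigrationCurve, tree: AnnotatedTree, out_path) -> None:
    """SVG line-bundle plot of the migration curves (matplotlib backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for nid, pt in curves.points.items():
        if pt.parent_id is None:
            continue
        parent = curves.points[pt.parent_id]
        ax.plot(
            [parent.cum_branch_length, pt.cum_branch_length],
            [parent.cum_distance_km, pt.cum_distance_km],
            color="steelblue", linewidth=0.8,
        )
    ax.set_xlabel("cumulative branch length (years)")
    ax.set_ylabel("cumulative great-circle distance (km)")
    fig.savefig(out_path, format="svg")
    plt.close(fig)
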