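"""Spatial clustering of sampled and ancestral localities.

Every node of the tree — tip or internal — is a locality.  Clusters can be
built automatically (K-means, optionally restricted to a lat/lon bounding
box) or from user geometry: anchor points (nearest-centroid assignment),
a rectangular grid, lasso polygons, or clades of the tree.  Cluster shapes
are reported as minimum convex hulls.

Distances here are plain Euclidean distances in (latitude, longitude)
degree space — the metric the anchor and K-means procedures are defined
with — so clusters at high latitude are stretched east-west relative to
ground distance.  Great-circle geometry is used only by the migration
module.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .errors import CoverageError, ParameterError
from .tree import AnnotatedTree

#: iteration cap guarding pathological cycling of Lloyd's algorithm under ties
KMEANS_MAX_ITER = 1000


@dataclass
class Locality:
    node_id: int
    latitude: float
    longitude: float
    is_tip: bool = False


@dataclass
class SpatialClustering:
    """A total assignment of localities to ``k`` clusters.

    ``centroids`` are arithmetic means of member coordinates (lat, lon);
    empty clusters carry NaN centroids.  ``hulls`` are counter-clockwise
    convex-hull vertex rings (degenerate rings of 1 or 2 vertices for
    point/collinear clusters).
    """

    k: int
    assignment: dict[int, int]
    centroids: list[tuple[float, float]]
    hulls: list[list[tuple[float, float]]]
    method: str
    bounds: tuple[float, float, float, float] | None = None  # lat_min, lat_max, lon_min, lon_max
    seed: int | None = None
    labels: list[str] = field(default_factory=list)
    #: K-means only: within-cluster sum of squares after each assignment step
    inertia_history: list[float] = field(default_factory=list)

    def members(self, cluster: int) -> list[int]:
        return [nid for nid, c in self.assignment.items() if c == cluster]


def tree_localities(tree: AnnotatedTree) -> list[Locality]:
    """All node localities of a tree, in preorder."""
    return [
        Locality(nid, tree.nodes[nid].latitude, tree.nodes[nid].longitude,
                 tree.nodes[nid].is_leaf)
        for nid in tree.preorder()
    ]


def _coords(localities: list[Locality]) -> np.ndarray:
    return np.array([[loc.latitude, loc.longitude] for loc in localities], float)


def _finish(localities, labels, k, method, bounds=None, seed=None, names=None):
    pts = _coords(localities)
    centroids, hulls = [], []
    for c in range(k):
        mask = labels == c
        if mask.any():
            centroids.append(tuple(pts[mask].mean(axis=0)))
            hulls.append(convex_hull([tuple(p) for p in pts[mask]]))
        else:
            centroids.append((float("nan"), float("nan")))
            hulls.append([])
    return SpatialClustering(
        k=k,
        assignment={loc.node_id: int(c) for loc, c in zip(localities, labels)},
        centroids=centroids,
        hulls=hulls,
        method=method,
        bounds=bounds,
        seed=seed,
        labels=list(names) if names else [str(c) for c in range(k)],
    )


def _nearest(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # squared Euclidean distances; ties resolved to the lowest center index
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


# ---------------------------------------------------------------------------
# K-means


def kmeans_cluster(
    localities: list[Locality],
    k: int,
    seed: int,
    bounds: tuple[float, float, float, float] | None = None,
) -> SpatialClustering:
    """Lloyd's algorithm with uniform-random initial centroids.

    Initial centroids are drawn uniformly inside the bounding box of the
    localities (intersected with ``bounds`` when given); localities are then
    assigned to their closest centroid by Euclidean distance and centroids
    recomputed, iterating until the assignment no longer changes.  The run
    is fully deterministic given ``seed``.  An emptied cluster is re-seeded
    at the point currently farthest from its own centroid, keeping k
    clusters alive.

    When ``bounds`` are given, localities outside the box are set aside in
    an extra residual cluster (index k) and only in-bounds points are
    clustered.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    pts = _coords(localities)
    in_bounds = np.ones(len(pts), bool)
    if bounds is not None:
        lat_min, lat_max, lon_min, lon_max = bounds
        in_bounds = (
            (pts[:, 0] >= lat_min) & (pts[:, 0] <= lat_max)
            & (pts[:, 1] >= lon_min) & (pts[:, 1] <= lon_max)
        )
    active = pts[in_bounds]
    if k > len(active):
        raise ParameterError(f"k={k} exceeds the {len(active)} available localities")

    rng = np.random.default_rng(seed)
    lo = active.min(axis=0)
    hi = active.max(axis=0)
    if bounds is not None:
        lo = np.maximum(lo, [bounds[0], bounds[2]])
        hi = np.minimum(hi, [bounds[1], bounds[3]])
    centers = rng.uniform(lo, hi, size=(k, 2))

    def objective(lbl, ctr):
        return float(((active - ctr[lbl]) ** 2).sum())

    labels = _nearest(active, centers)
    history = [objective(labels, centers)]
    for _ in range(KMEANS_MAX_ITER):
        for c in range(k):
            mask = labels == c
            if mask.any():
                centers[c] = active[mask].mean(axis=0)
            else:
                # re-seed at the point farthest from its assigned centroid
                far = ((active - centers[labels]) ** 2).sum(axis=1).argmax()
                centers[c] = active[far]
        new_labels = _nearest(active, centers)
        history.append(objective(new_labels, centers))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    full = np.full(len(pts), k, int)
    full[in_bounds] = labels
    k_total = k + 1 if (~in_bounds).any() else k
    names = [str(c) for c in range(k)] + (["out_of_bounds"] if k_total > k else [])
    result = _finish(localities, full, k_total, "kmeans", bounds, seed, names)
    result.inertia_history = history
    return result


def kmeans_inertia(localities: list[Locality], clustering: SpatialClustering) -> float:
    """Within-cluster sum of squared Euclidean distances (degree space)."""
    pts = _coords(localities)
    labels = np.array([clustering.assignment[loc.node_id] for loc in localities])
    total = 0.0
    for c in range(clustering.k):
        mask = labels == c
        if mask.any():
            total += float(((pts[mask] - pts[mask].mean(axis=0)) ** 2).sum())
    return total


# ---------------------------------------------------------------------------
# anchors / grid / polygons / clades


def anchor_assign(
    localities: list[Locality], anchors: list[tuple[float, float] | tuple[float, float, str]]
) -> SpatialClustering:
    """Assign each locality to the nearest anchor (Euclidean, degree space);
    ties go to the lowest anchor index.  k equals the number of anchors and
    clusters may be empty."""
    if not anchors:
        raise ParameterError("at least one anchor is required")
    centers = np.array([[a[0], a[1]] for a in anchors], float)
    labels = _nearest(_coords(localities), centers)
    names = [a[2] if len(a) > 2 else str(i) for i, a in enumerate(anchors)]
    return _finish(localities, labels, len(anchors), "anchors", names=names)


def grid_cluster(
    localities: list[Locality],
    n_lat: int,
    n_lon: int,
    bounds: tuple[float, float, float, float] | None = None,
) -> SpatialClustering:
    """Bin localities into an n_lat-by-n_lon grid over their bounding box.

    Cells are half-open [edge, next_edge) with the last cell closed, so a
    point on an interior edge belongs to the higher-index cell.  Only
    non-empty cells become clusters, numbered row-major (by latitude row,
    then longitude column).
    """
    if n_lat < 1 or n_lon < 1:
        raise ParameterError("grid dimensions must be >= 1")
    pts = _coords(localities)
    if bounds is not None:
        lat_min, lat_max, lon_min, lon_max = bounds
    else:
        lat_min, lat_max = pts[:, 0].min(), pts[:, 0].max()
        lon_min, lon_max = pts[:, 1].min(), pts[:, 1].max()
    lat_edges = np.linspace(lat_min, lat_max, n_lat + 1)
    lon_edges = np.linspace(lon_min, lon_max, n_lon + 1)
    # np.searchsorted with side='right' implements the half-open rule
    lat_idx = np.clip(np.searchsorted(lat_edges, pts[:, 0], side="right") - 1, 0, n_lat - 1)
    lon_idx = np.clip(np.searchsorted(lon_edges, pts[:, 1], side="right") - 1, 0, n_lon - 1)
    cells = lat_idx * n_lon + lon_idx
    occupied = sorted(set(int(c) for c in cells))
    renumber = {c: i for i, c in enumerate(occupied)}
    labels = np.array([renumber[int(c)] for c in cells])
    names = [f"r{c // n_lon}c{c % n_lon}" for c in occupied]
    return _finish(localities, labels, len(occupied), "grid",
                   (lat_min, lat_max, lon_min, lon_max), names=names)


def polygon_cluster(
    localities: list[Locality], polygons: list[list[tuple[float, float]]]
) -> SpatialClustering:
    """Lasso selection: each locality goes to the first polygon containing
    it (boundary inclusive); localities in no polygon form a residual
    cluster with index len(polygons)."""
    shapes = []
    for i, ring in enumerate(polygons):
        poly = Polygon([(lon, lat) for lat, lon in ring])
        if not poly.is_valid:
            raise ParameterError(f"polygon {i} is not simple (self-intersecting?)")
        shapes.append(poly)
    labels = []
    for loc in localities:
        pt = Point(loc.longitude, loc.latitude)
        for i, poly in enumerate(shapes):
            if poly.covers(pt):
                labels.append(i)
                break
        else:
            labels.append(len(shapes))
    names = [str(i) for i in range(len(shapes))] + ["residual"]
    return _finish(localities, np.array(labels), len(shapes) + 1, "polygon", names=names)


def clade_cluster(tree: AnnotatedTree, clade_roots: list[int]) -> SpatialClustering:
    """Cluster by clade membership: every node inside a selected clade joins
    that clade's cluster; everything else joins a residual cluster."""
    for i, a in enumerate(clade_roots):
        for j, b in enumerate(clade_roots):
            if i != j and b in tree.clade(a) and a != b:
                raise ParameterError(f"clade roots {a} and {b} are nested")
    localities = tree_localities(tree)
    residual = len(clade_roots)
    label_of = {nid: residual for nid in tree.nodes}
    for i, croot in enumerate(clade_roots):
        for nid in tree.clade(croot):
            label_of[nid] = i
    labels = np.array([label_of[loc.node_id] for loc in localities])
    names = [f"clade_{r}" for r in clade_roots] + ["residual"]
    return _finish(localities, labels, residual + 1, "clade", names=names)


# ---------------------------------------------------------------------------
# hulls


def convex_hull(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Minimum convex hull of (lat, lon) points as a counter-clockwise
    vertex ring.  Degenerate inputs give degenerate rings: one vertex for a
    single point (or coincident points), the two extremes for collinear
    points."""
    if not points:
        raise ParameterError("convex hull of an empty point set")
    hull = MultiPoint([(lon, lat) for lat, lon in points]).convex_hull
    if hull.geom_type == "Point":
        return [(hull.y, hull.x)]
    if hull.geom_type == "LineString":
        (x0, y0), (x1, y1) = hull.coords[0], hull.coords[-1]
        return [(y0, x0), (y1, x1)]
    ring = hull.exterior
    coords = list(ring.coords)[:-1]  # drop closing duplicate
    if not ring.is_ccw:
        coords.reverse()
    return [(lat, lon) for lon, lat in coords]


def hull_contains(hull: list[tuple[float, float]], point: tuple[float, float]) -> bool:
    """Boundary-inclusive point-in-hull test (works for degenerate rings)."""
    pt = Point(point[1], point[0])
    xy = [(lon, lat) for lat, lon in hull]
    if len(hull) == 1:
        return pt.distance(Point(xy[0])) < 1e-9
    if len(hull) == 2:
        return LineString(xy).distance(pt) < 1e-9
    return Polygon(xy).covers(pt)


# ---------------------------------------------------------------------------
# I/O


def clustering_to_csv(clustering: SpatialClustering, localities: list[Locality], out_path) -> None:
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "cluster", "latitude", "longitude"])
        for loc in localities:
            writer.writerow(
                [loc.node_id, clustering.assignment[loc.node_id],
                 repr(loc.latitude), repr(loc.longitude)]
            )


def clustering_from_csv(path) -> dict[int, int]:
    with open(path, newline="") as fh:
        return {int(r["node_id"]): int(r["cluster"]) for r in csv.DictReader(fh)}


def read_anchor_csv(path) -> list[tuple]:
    """Anchors from a headerless CSV of ``lat,lon[,color]`` rows."""
    anchors = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("lat", "latitude"):
                continue
            anchors.append(
                (float(row[0]), float(row[1]), *([row[2].strip()] if len(row) > 2 else []))
            )
    return anchors


def hulls_geojson(clustering: SpatialClustering) -> dict:
    features = []
    for c, hull in enumerate(clustering.hulls):
        if not hull:
            continue
        ring = [[lon, lat] for lat, lon in hull]
        if len(hull) >= 3:
            geometry = {"type": "Polygon", "coordinates": [ring + [ring[0]]]}
        elif len(hull) == 2:
            geometry = {"type": "LineString", "coordinates": ring}
        else:
            geometry = {"type": "Point", "coordinates": ring[0]}
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {
                    "cluster": c,
                    "label": clustering.labels[c] if c < len(clustering.labels) else str(c),
                    "size": len(clustering.members(c)),
                    "centroid": list(clustering.centroids[c]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_hulls_geojson(clustering: SpatialClustering, out_path) -> None:
    with open(out_path, "w") as fh:
        json.dump(hulls_geojson(clustering), fh, indent=1)


def check_coverage(clustering_assignment: dict[int, int], tree: AnnotatedTree) -> None:
    missing = [nid for nid in tree.nodes if nid not in clustering_assignment]
    if missing:
        raise CoverageError(
            f"clustering does not cover nodes {missing[:10]}"
            + ("..." if len(missing) > 10 else ""),
            missing,
        )
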