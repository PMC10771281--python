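"""Temporal brushing of the phylogeographic scenario.

A brush window is a closed time interval (optionally restricted to a
clade).  Every transition path falls in exactly one of five categories
relative to the window:

* ``complete`` — both the parent and the child node lie inside the window;
* ``total_partial`` — neither node is inside, but the window lies between
  them (the branch spans the whole window);
* ``downstream_partial`` — the parent is inside but the child is not
  (an outgoing migration);
* ``upstream_partial`` — the child is inside but the parent is not
  (an incoming migration);
* ``excluded`` — the branch does not overlap the window at all.

Partial paths are drawn proportionally to the branch duration inside the
window, with segment endpoints linearly interpolated in (lat, lon) at the
window edges.  Window membership is closed on both ends, so a node exactly
on a window edge counts as inside; consequently the included fractions of
two abutting windows sum exactly to the fraction of their union.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

from .errors import ParameterError
from .scenario import TransitionPath, scenario_geojson
from .tree import AnnotatedTree


@dataclass
class BrushWindow:
    t_start: float
    t_end: float
    clade_root: int | None = None

    def __post_init__(self):
        if self.t_start > self.t_end:
            raise ParameterError("brush window must have t_start <= t_end")


@dataclass
class SlicedPath:
    path: TransitionPath
    category: str
    included_fraction: float
    #: clipped (lat, lon) endpoints of the in-window segment; None if excluded
    segment: tuple[tuple[float, float], tuple[float, float]] | None


def _lerp(path: TransitionPath, t: float) -> tuple[float, float]:
    span = path.end_time - path.start_time
    f = 0.0 if span == 0 else (t - path.start_time) / span
    return (
        path.origin[0] + f * (path.destination[0] - path.origin[0]),
        path.origin[1] + f * (path.destination[1] - path.origin[1]),
    )


def classify_path(path: TransitionPath, window: BrushWindow) -> SlicedPath:
    """Categorize one path against a brush window and clip its geometry."""
    a, b = window.t_start, window.t_end
    s, e = path.start_time, path.end_time
    parent_in = a <= s <= b
    child_in = a <= e <= b

    if e == s:  # zero-length branch: an instant is either inside or not
        if parent_in:
            return SlicedPath(path, "complete", 1.0, (path.origin, path.destination))
        return SlicedPath(path, "excluded", 0.0, None)

    lo, hi = max(s, a), min(e, b)
    if lo > hi:
        return SlicedPath(path, "excluded", 0.0, None)
    fraction = (hi - lo) / (e - s)
    if parent_in and child_in:
        category = "complete"
    elif parent_in:
        category = "downstream_partial"
    elif child_in:
        category = "upstream_partial"
    else:
        category = "total_partial"
    segment = (_lerp(path, lo), _lerp(path, hi))
    return SlicedPath(path, category, fraction, segment)


def slice_scenario(
    paths: list[TransitionPath],
    window: BrushWindow,
    tree: AnnotatedTree | None = None,
) -> list[SlicedPath]:
    """Classify every path of the scenario against the window.

    With a clade-restricted window, paths outside the clade are excluded
    before temporal classification (``tree`` is required to resolve the
    clade).
    """
    allowed = None
    if window.clade_root is not None:
        if tree is None:
            raise ParameterError("clade-restricted windows need the source tree")
        allowed = set(tree.clade(window.clade_root)) - {window.clade_root}
    out = []
    for p in paths:
        if allowed is not None and p.child_id not in allowed:
            out.append(SlicedPath(p, "excluded", 0.0, None))
        else:
            out.append(classify_path(p, window))
    return out


def animation_frames(
    paths: list[TransitionPath],
    t_min: float,
    t_max: float,
    window_width: float,
    step: float,
    mode: str = "sliding",
    tree: AnnotatedTree | None = None,
    clade_root: int | None = None,
) -> list[tuple[BrushWindow, list[SlicedPath]]]:
    """Divide the phylogeographic process into consecutive stages.

    ``sliding`` mode yields windows [t, t + width] for t = t_min,
    t_min + step, ... while t < t_max; ``cumulative`` mode yields the
    gradual reveal [t_min, t] for t = t_min + step, t_min + 2 step, ...,
    capped at t_max.
    """
    if window_width <= 0 or step <= 0:
        raise ParameterError("window width and step must be positive")
    if mode not in ("sliding", "cumulative"):
        raise ParameterError(f"unknown animation mode {mode!r}")
    n = max(1, math.ceil((t_max - t_min) / step))
    frames = []
    for i in range(n):
        if mode == "sliding":
            t = t_min + i * step
            window = BrushWindow(t, t + window_width, clade_root)
        else:
            t = min(t_min + (i + 1) * step, t_max)
            window = BrushWindow(t_min, t, clade_root)
        frames.append((window, slice_scenario(paths, window, tree)))
    return frames


# ---------------------------------------------------------------------------
# export


def slice_geojson(slices: list[SlicedPath]) -> dict:
    features = []
    for sl in slices:
        if sl.segment is None:
            continue
        (lat0, lon0), (lat1, lon1) = sl.segment
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [[lon0, lat0], [lon1, lat1]]},
                "properties": {
                    "parent": sl.path.parent_id,
                    "child": sl.path.child_id,
                    "category": sl.category,
                    "included_fraction": sl.included_fraction,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_animation(frames, out_dir, mode: str = "sliding") -> dict:
    """Write numbered per-frame GeoJSON files plus a manifest; returns the
    manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"mode": mode, "frames": []}
    for i, (window, slices) in enumerate(frames):
        name = f"frame_{i:04d}.geojson"
        with open(os.path.join(out_dir, name), "w") as fh:
            json.dump(slice_geojson(slices), fh, indent=1)
        counts: dict[str, int] = {}
        for sl in slices:
            counts[sl.category] = counts.get(sl.category, 0) + 1
        manifest["frames"].append(
            {"file": name, "t_start": window.t_start, "t_end": window.t_end,
             "counts": counts}
        )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
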