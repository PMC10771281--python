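"""Reading and writing location-annotated NEXUS trees.

The supported dialect is the one produced by BEAST's TreeAnnotator: a NEXUS
file with a taxa block, a trees block with a ``Translate`` table, and a
single summary tree whose nodes carry bracketed metadata comments of the
form ``[&key=value,key2={v1,v2},...]``.  Continuous location coordinates
may be encoded as a pair of scalar keys (``location1``/``location2``), as a
two-element vector key (``location={lat,lon}``), or under names supplied by
the caller.  By BEAST convention latitude is the first coordinate; a swap
flag covers analyses that used the opposite order.

dendropy handles the NEXUS/Newick structure (translate tables, quoting,
rooting); this module parses the bracket-comment metadata itself so that
malformed annotations are reported with character offsets and uncommon keys
(HPD rings, discrete traits) are handled predictably.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from io import StringIO

import dendropy

from .errors import MissingAnnotationError, NexusFormatError
from .tree import AnnotatedTree, Node

_HPD_RE = re.compile(r"^(?P<stem>.+?)(?P<coord>[12])_(?P<rest>.*HPD.*)$")


@dataclass
class KeyConfig:
    """How location and trait annotations are named in the input.

    With all fields ``None`` the keys are autodetected from the root node's
    annotations, trying in order: paired scalar keys (a common stem followed
    by ``1`` and ``2``), then a two-element vector key.  ``swap_coordinates``
    flips the convention that latitude comes first.
    """

    latitude_key: str | None = None
    longitude_key: str | None = None
    vector_key: str | None = None
    paired_stem: str | None = None
    swap_coordinates: bool = False
    trait_key: str | None = None


# ---------------------------------------------------------------------------
# bracket-comment metadata


def parse_annotation_fields(text: str, base_offset: int = 0) -> dict[str, object]:
    """Parse the body of a ``[&...]`` comment (without the brackets or ``&``).

    Returns an ordered mapping of key to value, where a value is a float,
    a string, or a (possibly nested) list for ``{...}`` groups.  Raises
    :class:`NexusFormatError` with a character offset on malformed input.
    """
    fields: dict[str, object] = {}
    i, n = 0, len(text)
    while i < n:
        eq = text.find("=", i)
        if eq < 0:
            raise NexusFormatError(
                f"annotation field {text[i:]!r} lacks '='", base_offset + i
            )
        key = text[i:eq].strip()
        if not key:
            raise NexusFormatError("empty annotation key", base_offset + i)
        value, i = _parse_value(text, eq + 1, base_offset)
        fields[key] = value
        if i < n:
            if text[i] != ",":
                raise NexusFormatError(
                    f"expected ',' between annotation fields, got {text[i]!r}",
                    base_offset + i,
                )
            i += 1
    return fields


def _parse_value(text: str, i: int, base: int):
    n = len(text)
    if i < n and text[i] == "{":
        items, depth_start = [], i
        i += 1
        while True:
            if i >= n:
                raise NexusFormatError("unbalanced '{' in annotation", base + depth_start)
            if text[i] == "}":
                return items, i + 1
            item, i = _parse_value(text, i, base)
            items.append(item)
            if i < n and text[i] == ",":
                i += 1
    if i < n and text[i] == '"':
        end = text.find('"', i + 1)
        if end < 0:
            raise NexusFormatError("unterminated string in annotation", base + i)
        return text[i + 1 : end], end + 1
    j = i
    while j < n and text[j] not in ",}":
        j += 1
    raw = text[i:j].strip()
    try:
        return float(raw), j
    except ValueError:
        return raw, j


def _merge_node_comments(comments: list[str], doc: str) -> dict[str, object]:
    fields: dict[str, object] = {}
    for comment in comments:
        body = comment.lstrip("&")
        if not comment.startswith("&"):
            continue  # plain comment, not metadata
        offset = doc.find(comment)
        fields.update(parse_annotation_fields(body, offset if offset >= 0 else 0))
    return fields


# ---------------------------------------------------------------------------
# key resolution


def _autodetect(fields: dict[str, object], config: KeyConfig) -> KeyConfig:
    if config.latitude_key and config.longitude_key:
        return config
    if config.vector_key or config.paired_stem:
        return config
    # paired scalar keys first (BEAST's bivariate trait output)
    stems = []
    for key in fields:
        if key.endswith("1") and f"{key[:-1]}2" in fields:
            if isinstance(fields[key], float) and isinstance(fields[f"{key[:-1]}2"], float):
                stems.append(key[:-1])
    if stems:
        stems.sort(key=lambda s: (s.lower() != "location", s))
        return KeyConfig(
            paired_stem=stems[0],
            swap_coordinates=config.swap_coordinates,
            trait_key=config.trait_key,
        )
    # then a two-element numeric vector
    vectors = [
        k
        for k, v in fields.items()
        if isinstance(v, list) and len(v) == 2 and all(isinstance(x, float) for x in v)
        and "HPD" not in k
    ]
    if vectors:
        vectors.sort(key=lambda s: (s.lower() != "location", s))
        return KeyConfig(
            vector_key=vectors[0],
            swap_coordinates=config.swap_coordinates,
            trait_key=config.trait_key,
        )
    raise MissingAnnotationError(
        "could not autodetect location annotation keys; supply a KeyConfig"
    )


def _location_keys(config: KeyConfig) -> set[str]:
    keys = set()
    if config.paired_stem:
        keys |= {f"{config.paired_stem}1", f"{config.paired_stem}2"}
    if config.vector_key:
        keys.add(config.vector_key)
    if config.latitude_key:
        keys.add(config.latitude_key)
    if config.longitude_key:
        keys.add(config.longitude_key)
    return keys


def _extract_location(fields, config: KeyConfig, node_name):
    first = second = None
    if config.paired_stem:
        first = fields.get(f"{config.paired_stem}1")
        second = fields.get(f"{config.paired_stem}2")
    elif config.vector_key:
        vec = fields.get(config.vector_key)
        if isinstance(vec, list) and len(vec) == 2:
            first, second = vec
    else:
        first = fields.get(config.latitude_key)
        second = fields.get(config.longitude_key)
    if not (isinstance(first, float) and isinstance(second, float)):
        raise MissingAnnotationError(
            f"node {node_name!r} lacks a location annotation", node=node_name
        )
    lat, lon = (second, first) if config.swap_coordinates else (first, second)
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise MissingAnnotationError(
            f"node {node_name!r} has non-finite coordinates", node=node_name
        )
    return lat, lon


def _extract_hpd_polygons(fields, config: KeyConfig):
    """Pair ``<stem>1_*HPD*``/``<stem>2_*HPD*`` vector keys into (lat, lon) rings."""
    halves: dict[tuple[str, str], dict[str, list[float]]] = {}
    consumed = set()
    for key, value in fields.items():
        m = _HPD_RE.match(key)
        if not m or not isinstance(value, list):
            continue
        if not all(isinstance(x, float) for x in value):
            continue
        halves.setdefault((m.group("stem"), m.group("rest")), {})[m.group("coord")] = value
        consumed.add(key)
    rings = []
    for (_stem, _rest), coords in sorted(halves.items()):
        if set(coords) == {"1", "2"} and len(coords["1"]) == len(coords["2"]):
            rings.append(list(zip(coords["1"], coords["2"])))
    return rings, consumed


# ---------------------------------------------------------------------------
# parse / write


def parse_annotated_nexus(
    text: str,
    key_config: KeyConfig | None = None,
    most_recent_sampling_date: float | None = None,
) -> AnnotatedTree:
    """Parse a single-tree annotated NEXUS document into an :class:`AnnotatedTree`.

    Every node must resolve to finite latitude/longitude under ``key_config``
    (or autodetection).  Unknown annotation keys are preserved verbatim in
    ``node.extra``; HPD vector pairs become ``node.hpd_polygons``.
    """
    config = key_config or KeyConfig()
    try:
        trees = dendropy.TreeList.get(
            data=text, schema="nexus", extract_comment_metadata=False
        )
    except Exception as exc:  # dendropy raises several error types
        raise NexusFormatError(f"not a parseable NEXUS document: {exc}") from exc
    if len(trees) != 1:
        raise NexusFormatError(
            f"expected exactly one tree in the document, found {len(trees)}"
        )
    dtree = trees[0]

    dnodes = list(dtree.preorder_node_iter())
    all_fields = [_merge_node_comments(list(d.comments), text) for d in dnodes]
    resolved = config
    if not (config.latitude_key or config.vector_key or config.paired_stem):
        # detect from the first node carrying usable keys, so that a single
        # node with a deleted annotation is reported as missing, not as a
        # detection failure
        last_error = None
        for fields in all_fields:
            try:
                resolved = _autodetect(fields, config)
                break
            except MissingAnnotationError as exc:
                last_error = exc
        else:
            raise last_error

    nodes: dict[int, Node] = {}
    ids: dict[object, int] = {}
    for dnode, fields in zip(dnodes, all_fields):
        nid = len(nodes)
        ids[dnode] = nid
        name = dnode.taxon.label if dnode.taxon else f"internal node {nid}"
        lat, lon = _extract_location(fields, resolved, name)
        hpd, hpd_keys = _extract_hpd_polygons(fields, resolved)
        trait = None
        if resolved.trait_key is not None:
            raw = fields.get(resolved.trait_key)
            trait = None if raw is None else str(raw)
        skip = _location_keys(resolved) | hpd_keys
        if resolved.trait_key:
            skip.add(resolved.trait_key)
        extra = {k: _render_value(v) for k, v in fields.items() if k not in skip}
        parent = ids[dnode.parent_node] if dnode.parent_node is not None else None
        nodes[nid] = Node(
            id=nid,
            parent=parent,
            branch_length=None if parent is None else float(dnode.edge.length or 0.0),
            taxon_label=dnode.taxon.label if dnode.taxon else None,
            latitude=lat,
            longitude=lon,
            discrete_trait=trait,
            hpd_polygons=hpd,
            extra=extra,
        )
        if parent is not None:
            nodes[parent].children.append(nid)

    tree = AnnotatedTree(nodes, root_id=0, most_recent_sampling_date=most_recent_sampling_date)
    tree.validate()
    tree.key_config = resolved
    return tree


def _render_value(value) -> str:
    if isinstance(value, list):
        return "{" + ",".join(_render_value(v) for v in value) + "}"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


def _node_comment(node: Node, trait_key: str) -> str:
    parts = [f"location1={node.latitude!r}", f"location2={node.longitude!r}"]
    for k, ring in enumerate(node.hpd_polygons, start=1):
        lats = ",".join(repr(v) for v, _ in ring)
        lons = ",".join(repr(v) for _, v in ring)
        parts.append(f"location1_80%HPD_{k}={{{lats}}}")
        parts.append(f"location2_80%HPD_{k}={{{lons}}}")
    if node.discrete_trait is not None:
        parts.append(f'{trait_key}="{node.discrete_trait}"')
    for key, raw in node.extra.items():
        parts.append(f"{key}={raw}")
    return "[&" + ",".join(parts) + "]"


def write_annotated_nexus(tree: AnnotatedTree, trait_key: str = "trait") -> str:
    """Serialize to the TreeAnnotator NEXUS dialect; round-trips through
    :func:`parse_annotated_nexus`."""
    tips = tree.tips()
    out = StringIO()
    out.write("#NEXUS\n\nBegin taxa;\n")
    out.write(f"\tDimensions ntax={len(tips)};\n\tTaxlabels\n")
    for tip in tips:
        out.write(f"\t\t{_quote(tip.taxon_label or str(tip.id))}\n")
    out.write("\t\t;\nEnd;\n\nBegin trees;\n\tTranslate\n")
    numbers = {tip.id: k + 1 for k, tip in enumerate(tips)}
    rows = [
        f"\t\t{numbers[tip.id]} {_quote(tip.taxon_label or str(tip.id))}"
        for tip in tips
    ]
    out.write(",\n".join(rows))
    out.write("\n\t\t;\n")
    out.write("tree TREE1 = [&R] ")
    out.write(_newick(tree, tree.root_id, numbers, trait_key))
    out.write(";\nEnd;\n")
    return out.getvalue()


def _newick(tree: AnnotatedTree, nid: int, numbers, trait_key, annotate=True) -> str:
    node = tree.nodes[nid]
    if node.is_leaf:
        label = str(numbers[nid]) if numbers else _quote(node.taxon_label or str(nid))
    else:
        label = (
            "(" + ",".join(_newick(tree, c, numbers, trait_key, annotate) for c in node.children) + ")"
        )
    comment = _node_comment(node, trait_key) if annotate else ""
    brlen = "" if node.branch_length is None else f":{node.branch_length!r}"
    return f"{label}{comment}{brlen}"


def write_newick(tree: AnnotatedTree) -> str:
    """Plain Newick with taxon labels and branch lengths, annotations stripped."""
    return _newick(tree, tree.root_id, None, "trait", annotate=False) + ";"


def node_times(tree: AnnotatedTree) -> dict[int, float]:
    """Absolute node times in decimal years (see :meth:`AnnotatedTree.node_times`)."""
    return tree.node_times()
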