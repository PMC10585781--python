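"""Per-frame ternary vessel tree built from spatial relations.

Contrast arrives through the catheter, which projects near the upper
left corner of the image, so the root segment is the one whose start is
closest (city-block) to the origin.  A segment becomes the child of a
node when the city-block distance between the node's end point and the
segment's start point is at most ``d_n_threshold`` (10 px by default);
a node keeps at most three children (the tree degree is 3).  Sibling
order follows the sign of the cross product

    V = (x2 - x1)(y3 - y2) - (y2 - y1)(x3 - x2)

evaluated in image coordinates (y down): V > 0 puts p2 first, V < 0
puts p3 first.  IDs are reassigned top-to-bottom (level order); the
smaller the ID the earlier the vessel fills during angiography.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field

from angiotrack.segments import VesselSegment

logger = logging.getLogger("angiotrack.tree")


@dataclass
class TreeNode:
    segment: VesselSegment
    parent: int | None = None
    children: list[int] = field(default_factory=list)


@dataclass
class VesselTree:
    """Ternary tree (or forest, if segments are disconnected) of one frame."""

    nodes: dict[int, TreeNode]
    roots: list[int]

    @property
    def root_id(self) -> int:
        return self.roots[0]

    def edges(self) -> set[tuple[int, int]]:
        return {(nid, c) for nid, node in self.nodes.items() for c in node.children}


def spatial_distance(end: tuple[float, float], start: tuple[float, float]) -> float:
    """City-block (Manhattan) distance d_n = |x_s - x_e| + |y_s - y_e|."""
    return abs(start[0] - end[0]) + abs(start[1] - end[1])


def find_root(segments: list[VesselSegment]) -> int:
    """Provisional id of the catheter-proximal segment: the one whose
    start minimizes the city-block distance to the image origin (ties:
    smaller y, then smaller x)."""
    if not segments:
        raise ValueError("find_root: no segments")
    best = min(segments,
               key=lambda s: (s.start[0] + s.start[1], s.start[1], s.start[0]))
    return best.id


def _cross(p1, p2, p3) -> float:
    return (p2[0] - p1[0]) * (p3[1] - p2[1]) - (p2[1] - p1[1]) * (p3[0] - p2[0])


def order_children(
    p1: tuple[float, float], child_starts: list[tuple[float, float]]
) -> list[int]:
    """Return the indices of ``child_starts`` in sibling order.

    Two children p2, p3: V > 0 means p2 comes first, V < 0 means p3
    does; collinear children (V = 0) fall back to ascending x then y.
    Three children are ordered by applying the rule pairwise.
    """
    if len(child_starts) <= 1:
        return list(range(len(child_starts)))

    def cmp(i: int, j: int) -> int:
        v = _cross(p1, child_starts[i], child_starts[j])
        if v > 0:
            return -1
        if v < 0:
            return 1
        if child_starts[i] == child_starts[j]:
            return 0
        return -1 if child_starts[i] < child_starts[j] else 1

    return sorted(range(len(child_starts)), key=functools.cmp_to_key(cmp))


def _departure_point(seg: VesselSegment) -> tuple[float, float]:
    """A point a few pixels along the segment from its start, carrying
    the direction in which the vessel leaves the junction."""
    k = min(5, len(seg.path.pixels) - 1)
    return seg.path.pixels[k]


def build_tree(
    segments: list[VesselSegment], d_n_threshold: float = 10.0
) -> VesselTree:
    """Assemble the vessel tree of one frame and reassign IDs.

    Breadth-first from the root: unassigned segments whose start lies
    within ``d_n_threshold`` (inclusive) of the current node's end become
    its children (the three nearest if more qualify), ordered by the
    cross-product rule.  Segments never reached become roots of further
    trees of a forest (logged).  IDs are rewritten in level order across
    the forest, so the root holds the smallest ID and IDs increase with
    tree level; the segments' ``id``, ``parent`` and ``children`` fields
    are updated in place.
    """
    if not segments:
        raise ValueError("build_tree: no segments")
    by_id = {s.id: s for s in segments}
    unassigned = set(by_id)
    parent_of: dict[int, int | None] = {}
    children_of: dict[int, list[int]] = {i: [] for i in by_id}
    roots: list[int] = []
    level_of: dict[int, int] = {}
    order: list[int] = []          # visit order = level order

    while unassigned:
        root = find_root([by_id[i] for i in sorted(unassigned)])
        if roots:
            logger.info("orphan segment %d starts a new tree of the forest", root)
        roots.append(root)
        unassigned.discard(root)
        parent_of[root] = None
        level_of[root] = 0
        queue = [root]
        while queue:
            nid = queue.pop(0)
            order.append(nid)
            node_seg = by_id[nid]
            # a candidate may present either endpoint at the junction; it
            # is oriented afterwards so its start sits at the attachment
            cand = []
            for c in sorted(unassigned):
                d_fwd = spatial_distance(node_seg.end, by_id[c].start)
                d_rev = spatial_distance(node_seg.end, by_id[c].end)
                d = min(d_fwd, d_rev)
                if d <= d_n_threshold:
                    cand.append((d, c, d_rev < d_fwd))
            cand.sort()
            cand = cand[:3]
            if cand:
                for _, c, flip in cand:
                    if flip:
                        by_id[c].reverse_in_place()
                # children often share the junction pixel as their start;
                # order them by a departure point a few pixels in
                points = [_departure_point(by_id[c]) for _, c, _ in cand]
                perm = order_children(node_seg.end, points)
                kids = [cand[k][1] for k in perm]
                for c in kids:
                    unassigned.discard(c)
                    parent_of[c] = nid
                    level_of[c] = level_of[nid] + 1
                children_of[nid] = kids
                queue.extend(kids)

    # level-order ID reassignment across the forest
    pos = {i: k for k, i in enumerate(order)}
    order.sort(key=lambda i: (level_of[i], pos[i]))
    new_id = {old: new for new, old in enumerate(order)}
    nodes: dict[int, TreeNode] = {}
    for old, seg in by_id.items():
        seg.id = new_id[old]
        seg.parent = None if parent_of[old] is None else new_id[parent_of[old]]
        seg.children = [new_id[c] for c in children_of[old]]
    for old, seg in by_id.items():
        nodes[seg.id] = TreeNode(segment=seg, parent=seg.parent,
                                 children=list(seg.children))
    return VesselTree(nodes=nodes, roots=[new_id[r] for r in roots])
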