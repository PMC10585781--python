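"""Centerline extraction from binary vessel masks.

Implements the classic two-subiteration thinning of Zhang and Suen,
a staircase-smoothing pass, keypoint (endpoint / intersection) detection
on the single-pixel skeleton, splitting of the skeleton into per-vessel
centerline paths, burr removal and skeleton repair.

Pixel neighborhoods follow the usual convention: for a pixel p1, p2 is
the pixel directly above it and p3..p9 continue clockwise, so

    p9 p2 p3
    p8 p1 p4
    p7 p6 p5

N(p1) is the number of foreground neighbors and S(p1) the number of 0->1
transitions in the cyclic sequence p2, p3, ..., p9, p2.

Coordinates are (x, y) = (column, row), 0-based, origin at the top-left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger("angiotrack.skeleton")

# (dy, dx) offsets for p2..p9 (p2 above, then clockwise)
_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass(frozen=True)
class KeyPointSet:
    """Skeleton keypoints: endpoints and (deduplicated) intersections.

    Coordinates are (x, y) tuples.
    """

    endpoints: list[tuple[int, int]]
    intersections: list[tuple[int, int]]


@dataclass
class CenterlinePath:
    """Ordered single-pixel centerline of one separated vessel.

    ``pixels`` holds (x, y) tuples; consecutive pixels are 8-adjacent.
    When a path terminates at a junction, the shared junction pixel is
    included in ``pixels`` but flagged so it is not counted in the
    vessel's own length (``n_own``).
    """

    pixels: list[tuple[int, int]]
    frame_index: int = 0
    junction_start: bool = False
    junction_end: bool = False
    is_closed: bool = False

    @property
    def n_own(self) -> int:
        """Pixel count excluding junction pixels shared with other paths."""
        return len(self.pixels) - int(self.junction_start) - int(self.junction_end)

    def reversed(self) -> "CenterlinePath":
        return CenterlinePath(
            pixels=list(reversed(self.pixels)),
            frame_index=self.frame_index,
            junction_start=self.junction_end,
            junction_end=self.junction_start,
            is_closed=self.is_closed,
        )


def _neighbor_stack(img: np.ndarray) -> np.ndarray:
    """Stack of the eight neighbor images p2..p9, zero-padded at borders."""
    padded = np.pad(img, 1)
    h, w = img.shape
    return np.stack(
        [padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w] for dy, dx in _OFFSETS]
    )


def _counts(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (p2..p9 stack, N(p1), S(p1)) for every pixel."""
    nb = _neighbor_stack(img)
    n = nb.sum(axis=0)
    cyc = np.concatenate([nb, nb[:1]], axis=0)
    s = ((cyc[:-1] == 0) & (cyc[1:] == 1)).sum(axis=0)
    return nb, n, s


def thin(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a single-pixel skeleton (Zhang–Suen).

    Alternates two subiterations until a full pass deletes nothing.  A
    pixel is deleted in the first subiteration when 2 <= N(p1) <= 6,
    S(p1) = 1, p2*p4*p6 = 0 and p4*p6*p8 = 0; the second subiteration
    replaces the last two conditions by p2*p4*p8 = 0 and p2*p6*p8 = 0.
    Deletions within a subiteration are simultaneous.

    An empty mask yields an empty skeleton.
    """
    img = (np.asarray(mask) > 0).astype(np.uint8)
    if img.ndim != 2:
        raise ValueError("mask must be 2-D")
    while True:
        changed = False
        for sub in (0, 1):
            nb, n, s = _counts(img)
            p2, p4, p6, p8 = nb[0], nb[2], nb[4], nb[6]
            if sub == 0:
                extra = (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
            else:
                extra = (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
            kill = (img == 1) & (n >= 2) & (n <= 6) & (s == 1) & extra
            if kill.any():
                img[kill] = 0
                changed = True
        if not changed:
            return img


def _is_locally_connected(img: np.ndarray, y: int, x: int) -> bool:
    """True if the foreground neighbors of (y, x) stay 8-connected
    within the 3x3 ring after (y, x) itself is removed."""
    h, w = img.shape
    ring = [(dy, dx) for dy, dx in _OFFSETS
            if 0 <= y + dy < h and 0 <= x + dx < w and img[y + dy, x + dx]]
    if len(ring) <= 1:
        return True
    # union-find over at most 8 ring pixels
    parent = list(range(len(ring)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ring)):
        for j in range(i + 1, len(ring)):
            if max(abs(ring[i][0] - ring[j][0]), abs(ring[i][1] - ring[j][1])) <= 1:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(ring))}) == 1


def remove_staircase(skel: np.ndarray) -> np.ndarray:
    """Delete staircase corner pixels from a thinned skeleton.

    A degree-2 pixel p_i with ordered-path neighbors p_{i-1}, p_{i+1}
    is a corner when either coordinate pattern holds (in either walk
    direction):

      * x_{i-1} = x_i - 1, y_{i-1} = y_i, x_i = x_{i+1}, y_i = y_{i+1} + 1
      * x_{i-1} = x_i, y_i = y_{i-1} + 1, x_i = x_{i+1} - 1, y_i = y_{i+1}

    One deterministic scan-order pass; a deletion that would split the
    skeleton component is skipped.
    """
    img = (np.asarray(skel) > 0).astype(np.uint8)
    h, w = img.shape

    def matches(grid: np.ndarray, y: int, x: int) -> bool:
        nbrs = [(y + dy, x + dx) for dy, dx in _OFFSETS
                if 0 <= y + dy < h and 0 <= x + dx < w and grid[y + dy, x + dx]]
        for my, mx in nbrs:
            for py, px in nbrs:
                if (my, mx) == (py, px):
                    continue
                pat1 = (mx == x - 1 and my == y and x == px and y == py + 1)
                pat2 = (mx == x and y == my + 1 and x == px - 1 and y == py)
                if pat1 or pat2:
                    return True
        return False

    ys, xs = np.nonzero(img)
    cand = [(y, x) for y, x in zip(ys.tolist(), xs.tolist()) if matches(img, y, x)]
    out = img.copy()
    for y, x in cand:
        # re-verify on the evolving image, then guard connectivity
        if matches(out, y, x) and _is_locally_connected(out, y, x):
            out[y, x] = 0
    return out


def _junction_mask(skel: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least three skeleton neighbors."""
    _, n, _ = _counts(skel)
    return (skel == 1) & (n >= 3)


def _cluster_representatives(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 8-adjacent (y, x) points; keep the pixel nearest each
    cluster centroid (ties broken in scan order)."""
    if not points:
        return []
    pts = sorted(points)
    index = {p: i for i, p in enumerate(pts)}
    parent = list(range(len(pts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (y, x) in pts:
        for dy, dx in _OFFSETS:
            q = (y + dy, x + dx)
            if q in index:
                parent[find(index[(y, x)])] = find(index[q])
    clusters: dict[int, list[tuple[int, int]]] = {}
    for i, p in enumerate(pts):
        clusters.setdefault(find(i), []).append(p)
    reps = []
    for members in clusters.values():
        cy = sum(p[0] for p in members) / len(members)
        cx = sum(p[1] for p in members) / len(members)
        reps.append(min(members, key=lambda p: ((p[0] - cy) ** 2 + (p[1] - cx) ** 2,
                                                p[0], p[1])))
    return sorted(reps)


def detect_keypoints(skel: np.ndarray) -> KeyPointSet:
    """Find endpoints and intersections of a single-pixel skeleton.

    Endpoints have exactly one foreground 8-neighbor.  Intersection
    pixels satisfy all of

        N(p1) >= 3,
        p3+p4+p5 <= 1,  p5+p6+p7 <= 1,  p7+p8+p9 <= 1,  p9+p2+p3 <= 1,

    which rejects the near-junction pixels whose neighbor count alone
    would look like a crossing.  Adjacent qualifying pixels (thinning can
    leave 2-px junction clusters) are merged to the one nearest their
    centroid.  Returned coordinates are (x, y).
    """
    img = (np.asarray(skel) > 0).astype(np.uint8)
    nb, n, _ = _counts(img)
    p2, p3, p4, p5, p6, p7, p8, p9 = nb
    ends = (img == 1) & (n == 1)
    inter = (
        (img == 1)
        & (n >= 3)
        & (p3 + p4 + p5 <= 1)
        & (p5 + p6 + p7 <= 1)
        & (p7 + p8 + p9 <= 1)
        & (p9 + p2 + p3 <= 1)
    )
    ys, xs = np.nonzero(ends)
    endpoints = [(int(x), int(y)) for y, x in zip(ys, xs)]
    reps = _cluster_representatives(list(zip(*np.nonzero(inter))))
    intersections = [(int(x), int(y)) for y, x in reps]
    return KeyPointSet(endpoints=endpoints, intersections=intersections)


def split_segments(
    skel: np.ndarray,
    kps: KeyPointSet,
    frame_index: int = 0,
    merge_connector_len: int = 6,
) -> list[CenterlinePath]:
    """Partition a skeleton into per-vessel centerline paths.

    The skeleton is cut at junction pixels (>= 3 skeleton neighbors);
    each remaining chain becomes one ordered path, extended with the
    representative pixel of any junction cluster it touches (junction
    pixels are therefore shared between incident paths).  Thinning can
    break one anatomical bifurcation into two junction clusters a few
    pixels apart; a connector chain shorter than ``merge_connector_len``
    whose both ends touch junctions is absorbed into a single junction
    cluster rather than reported as a vessel.  A cyclic component
    without keypoints is emitted as a single closed path with a warning.
    """
    img = (np.asarray(skel) > 0).astype(np.uint8)
    junc = _junction_mask(img).copy()
    for _ in range(10):
        absorbed = _absorb_short_connectors(img, junc, merge_connector_len)
        if not absorbed:
            break
    jpoints = list(zip(*np.nonzero(junc)))
    jreps = _cluster_representatives(jpoints)
    # map every junction pixel to its cluster representative
    rep_of: dict[tuple[int, int], tuple[int, int]] = {}
    if jpoints:
        lbl, _ = ndimage.label(junc, structure=np.ones((3, 3), dtype=int))
        rep_by_label = {lbl[r] : r for r in jreps}
        for p in jpoints:
            rep_of[p] = rep_by_label[lbl[p]]

    chains_img = img.copy()
    for (y, x) in jpoints:
        chains_img[y, x] = 0

    lbl, nlab = ndimage.label(chains_img, structure=np.ones((3, 3), dtype=int))
    paths: list[CenterlinePath] = []
    h, w = img.shape

    def neighbors_in(py: int, px: int, grid: np.ndarray) -> list[tuple[int, int]]:
        return [(py + dy, px + dx) for dy, dx in _OFFSETS
                if 0 <= py + dy < h and 0 <= px + dx < w and grid[py + dy, px + dx]]

    for comp in range(1, nlab + 1):
        comp_mask = lbl == comp
        ys, xs = np.nonzero(comp_mask)
        members = sorted(zip(ys.tolist(), xs.tolist()))
        deg = {p: len(neighbors_in(*p, comp_mask)) for p in members}
        starts = [p for p in members if deg[p] <= 1]
        closed = False
        if starts:
            start = starts[0]
        else:  # cycle
            closed = True
            start = members[0]
            logger.warning("cyclic skeleton component of %d px emitted as closed path",
                           len(members))
        order = [start]
        visited = {start}
        cur = start
        while True:
            nxt = [q for q in neighbors_in(*cur, comp_mask) if q not in visited]
            if not nxt:
                break
            # prefer 4-adjacent continuation for a stable walk
            nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
            cur = nxt[0]
            order.append(cur)
            visited.add(cur)
        if closed:
            paths.append(CenterlinePath(
                pixels=[(int(x), int(y)) for y, x in order],
                frame_index=frame_index, is_closed=True))
            continue
        # attach junction representatives at either end
        first, last = order[0], order[-1]
        jstart = jend = False
        sreps = sorted({rep_of[q] for q in neighbors_in(*first, junc)})
        if sreps:
            order.insert(0, sreps[0])
            jstart = True
        ereps = [r for r in sorted({rep_of[q] for q in neighbors_in(*last, junc)})
                 if r != order[0]]  # 1-px chain may touch one cluster twice
        if ereps:
            order.append(ereps[0])
            jend = True
        paths.append(CenterlinePath(
            pixels=[(int(x), int(y)) for y, x in order],
            frame_index=frame_index,
            junction_start=jstart, junction_end=jend))
    paths.sort(key=lambda p: (p.pixels[0][1], p.pixels[0][0]))
    return paths


def _absorb_short_connectors(
    img: np.ndarray, junc: np.ndarray, max_len: int
) -> bool:
    """Mark chains of < ``max_len`` pixels joining two junction clusters
    as junction pixels themselves (in place).  Returns True if any chain
    was absorbed."""
    if not junc.any() or max_len <= 0:
        return False
    chains = img.astype(bool) & ~junc
    lbl, nlab = ndimage.label(chains, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        return False
    jlbl, _ = ndimage.label(junc, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(chains, lbl, index=np.arange(1, nlab + 1))
    slices = ndimage.find_objects(lbl)
    absorbed = False
    h, w = lbl.shape
    for comp in np.nonzero(sizes < max_len)[0] + 1:
        sy, sx = slices[comp - 1]
        sy = slice(max(0, sy.start - 1), min(h, sy.stop + 1))
        sx = slice(max(0, sx.start - 1), min(w, sx.stop + 1))
        comp_mask = lbl[sy, sx] == comp
        dil = ndimage.binary_dilation(comp_mask, structure=np.ones((3, 3), dtype=bool))
        touching = set(np.unique(jlbl[sy, sx][dil])) - {0}
        if len(touching) >= 2:
            junc[sy, sx] |= comp_mask
            absorbed = True
    return absorbed


def remove_burrs(paths: list[CenterlinePath], min_len: int = 6) -> list[CenterlinePath]:
    """Drop burr paths: spurious free-ended branches shorter than
    ``min_len`` own pixels (junction pixels shared with other vessels do
    not count).  Paths of exactly ``min_len`` pixels are kept, as are
    short chains joining two junctions (they are connectors, not
    spurs)."""
    return [p for p in paths
            if p.n_own >= min_len or (p.junction_start and p.junction_end)]


def deburred_skeleton(
    skel: np.ndarray, removed: list[CenterlinePath]
) -> np.ndarray:
    """Skeleton minus the own pixels of the removed burr paths (their
    junction-shared end pixels stay, since other vessels own them too).

    Junction-cluster remnants of a removed spur (former junction pixels
    that now only pad the surviving vessel) are pruned when their removal
    keeps the neighborhood connected, so a dissolved junction really
    disappears.
    """
    src = (np.asarray(skel) > 0).astype(np.uint8)
    out = src.copy()
    deleted: set[tuple[int, int]] = set()
    for p in removed:
        own = p.pixels[int(p.junction_start): len(p.pixels) - int(p.junction_end)]
        for x, y in own:
            out[y, x] = 0
            deleted.add((y, x))
    if not deleted:
        return out
    was_junction = _junction_mask(src)
    h, w = out.shape
    for _ in range(8):
        changed = False
        ys, xs = np.nonzero(out)
        for y, x in sorted(zip(ys.tolist(), xs.tolist())):
            if not was_junction[y, x]:
                continue
            touches = any((y + dy, x + dx) in deleted for dy, dx in _OFFSETS)
            if not touches:
                continue
            nbrs = sum(1 for dy, dx in _OFFSETS
                       if 0 <= y + dy < h and 0 <= x + dx < w and out[y + dy, x + dx])
            if nbrs >= 2 and _is_locally_connected(out, y, x):
                out[y, x] = 0
                deleted.add((y, x))
                changed = True
        if not changed:
            break
    return out


def repair(original: np.ndarray, deburred: np.ndarray) -> np.ndarray:
    """Restore wrongly deleted junction pixels after burr removal.

    ``deleted`` = original minus deburred.  A deleted pixel is restored
    when it is 8-adjacent to two endpoints of *different* deburred
    components, both lying within 2 px of a former intersection of the
    original skeleton — i.e. it re-joins the head and tail of a vessel
    that burr removal cut apart.  Deleted pixels not adjacent to any
    endpoint are never restored.
    """
    orig = (np.asarray(original) > 0).astype(np.uint8)
    deb = (np.asarray(deburred) > 0).astype(np.uint8)
    deleted = (orig == 1) & (deb == 0)
    if not deleted.any():
        return deb.copy()
    jy, jx = np.nonzero(_junction_mask(orig))
    former = np.stack([jy, jx], axis=1) if jy.size else np.empty((0, 2))
    _, n_deb, _ = _counts(deb)
    ey, ex = np.nonzero((deb == 1) & (n_deb == 1))
    eligible = set()
    for y, x in zip(ey.tolist(), ex.tolist()):
        if former.size and np.min(
            np.hypot(former[:, 0] - y, former[:, 1] - x)
        ) <= 2.0:
            eligible.add((y, x))
    lbl, _ = ndimage.label(deb, structure=np.ones((3, 3), dtype=int))
    out = deb.copy()
    h, w = deb.shape
    # candidate pixels grouped by the component pair they would rejoin;
    # the best-aligned one (smallest total distance to the endpoints it
    # touches) is restored per pair
    groups: dict[frozenset[int], list[tuple[float, int, int]]] = {}
    for y, x in sorted(zip(*np.nonzero(deleted))):
        comps: set[int] = set()
        score = 0.0
        for dy, dx in _OFFSETS:
            q = (y + dy, x + dx)
            if 0 <= q[0] < h and 0 <= q[1] < w and q in eligible:
                comps.add(int(lbl[q]))
                score += float(np.hypot(dy, dx))
        if len(comps) >= 2:
            groups.setdefault(frozenset(comps), []).append((score, y, x))
    merged: list[set[int]] = []
    for pair in sorted(groups, key=sorted):
        if any(pair <= m for m in merged):
            continue
        _, y, x = min(groups[pair])
        out[y, x] = 1
        for m in merged:
            if m & pair:
                m |= pair
                break
        else:
            merged.append(set(pair))
    return out
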