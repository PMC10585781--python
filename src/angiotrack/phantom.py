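"""Seeded synthetic angiography phantoms with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes about segmented coronary frames: branching vessel trees with
pixel widths of roughly 3–15, bounded rigid inter-frame translation,
focal narrowings (static stenosis) and periodic narrowings spanning
several frames (the myocardial-bridge "milking effect").  Every sequence
comes with a truth sidecar: per-frame centerlines and widths, the
parent–child edges, cross-frame correspondences and per-lesion stenosis
degrees.

Rendering stamps a disc of diameter equal to the local vessel width at
centerline samples spaced one pixel apart, which keeps the rendered
width analytically known.  A lesion narrows the width with a
raised-cosine dip over its extent:

    w(s) = base * (1 - degree * (1 + cos(2*pi*(s - s0)/extent)) / 2)

for |s - s0| <= extent/2, and a periodic lesion's degree oscillates over
the frames as  degree(t) = severity * (1 + cos(2*pi*t/period)) / 2.

Coordinates are (x, y) = (column, row), 0-based, origin top-left.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("angiotrack.phantom")


class PhantomValidationError(ValueError):
    """A phantom spec violates an invariant; the message names the field."""


@dataclass
class CenterlineSpec:
    """One vessel: a polyline of (x, y) control points with a base width."""

    points: list[tuple[float, float]]
    base_width: float
    parent: int | None = None


@dataclass
class LesionSpec:
    """A focal narrowing on one segment.

    ``position`` is the fractional arc-length of the lesion center,
    ``severity`` the maximal fractional width reduction, ``extent`` the
    lesion length in pixels.  Periodic lesions modulate over the frames
    with period ``period_frames`` (a myocardial bridge); static lesions
    keep their severity in every frame.
    """

    segment: int
    position: float
    severity: float
    extent: float
    periodic: bool = False
    period_frames: int = 6


@dataclass
class PhantomSpec:
    image_height: int = 256
    image_width: int = 256
    seed: int = 0
    segments: list[CenterlineSpec] = field(default_factory=list)
    motion_per_frame: tuple[float, float] = (0.0, 0.0)
    n_frames: int = 1
    stenoses: list[LesionSpec] = field(default_factory=list)


@dataclass
class PhantomTruth:
    """Ground-truth sidecar: one record per frame plus the lesion table."""

    image_height: int
    image_width: int
    n_frames: int
    frames: list[dict]
    lesions: list[dict]

    def to_dict(self) -> dict:
        return {
            "image_height": self.image_height,
            "image_width": self.image_width,
            "n_frames": self.n_frames,
            "frames": self.frames,
            "lesions": self.lesions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        validate_truth(d)
        return cls(**{k: d[k] for k in
                      ("image_height", "image_width", "n_frames", "frames", "lesions")})


def validate_truth(d: dict) -> None:
    """Check a truth dictionary against the published sidecar schema."""
    for key in ("image_height", "image_width", "n_frames", "frames", "lesions"):
        if key not in d:
            raise PhantomValidationError(f"truth: missing key '{key}'")
    if len(d["frames"]) != d["n_frames"]:
        raise PhantomValidationError("truth: one frame record per frame required")
    for t, fr in enumerate(d["frames"]):
        for key in ("frame_index", "segments", "bifurcations", "endpoints", "lesions"):
            if key not in fr:
                raise PhantomValidationError(f"truth: frame {t} missing '{key}'")
        ids = [s["correspondence_id"] for s in fr["segments"]]
        if len(ids) != len(set(ids)):
            raise PhantomValidationError(
                f"truth: frame {t} correspondence ids are not unique")
        for s in fr["segments"]:
            for key in ("index", "correspondence_id", "parent", "centerline",
                        "widths", "clipped"):
                if key not in s:
                    raise PhantomValidationError(
                        f"truth: frame {t} segment record missing '{key}'")
            if len(s["centerline"]) != len(s["widths"]):
                raise PhantomValidationError(
                    f"truth: frame {t} centerline/width length mismatch")


def validate_spec(spec: PhantomSpec) -> None:
    if spec.n_frames < 1:
        raise PhantomValidationError("n_frames must be >= 1")
    if spec.image_height < 3 or spec.image_width < 3:
        raise PhantomValidationError("image_height/image_width must be >= 3")
    if not spec.segments:
        raise PhantomValidationError("segments must be non-empty")
    for i, seg in enumerate(spec.segments):
        if seg.base_width < 3:
            raise PhantomValidationError(f"segments[{i}].base_width must be >= 3")
        if len(seg.points) < 2:
            raise PhantomValidationError(f"segments[{i}].points needs >= 2 points")
        if seg.parent is not None:
            if not (0 <= seg.parent < len(spec.segments)) or seg.parent == i:
                raise PhantomValidationError(f"segments[{i}].parent out of range")
            p = spec.segments[seg.parent]
            x0, y0 = seg.points[0]
            d = min(abs(x0 - px) + abs(y0 - py) for px, py in (p.points[0], p.points[-1]))
            if d > 10:
                raise PhantomValidationError(
                    f"segments[{i}].points must begin within 10 Manhattan px "
                    f"of parent endpoints (got {d:.1f})")
    for j, les in enumerate(spec.stenoses):
        if not (0 <= les.segment < len(spec.segments)):
            raise PhantomValidationError(f"stenoses[{j}].segment out of range")
        if not (0.0 < les.severity < 1.0):
            raise PhantomValidationError(
                f"stenoses[{j}].severity must be strictly between 0 and 1")
        if not (0.0 <= les.position <= 1.0):
            raise PhantomValidationError(f"stenoses[{j}].position must be in [0, 1]")
        if les.extent <= 0:
            raise PhantomValidationError(f"stenoses[{j}].extent must be positive")
        if les.periodic and les.period_frames < 2:
            raise PhantomValidationError(f"stenoses[{j}].period_frames must be >= 2")


def _sample_polyline(
    points: list[tuple[float, float]], step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ``step``-px arc length; returns
    (samples Nx2, arc lengths N)."""
    pts = np.asarray(points, dtype=float)
    d = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    total = cum[-1]
    if total <= 0:
        return pts[:1], np.zeros(1)
    s = np.arange(0.0, total + step / 2, step)
    s[-1] = min(s[-1], total)
    xs = np.interp(s, cum, pts[:, 0])
    ys = np.interp(s, cum, pts[:, 1])
    return np.stack([xs, ys], axis=1), s


def lesion_degree(les: LesionSpec, frame: int) -> float:
    """True stenosis degree of a lesion at a frame (fraction 0–1)."""
    if not les.periodic:
        return les.severity
    return les.severity * (1.0 + math.cos(2.0 * math.pi * frame / les.period_frames)) / 2.0


def _segment_widths(
    seg_index: int,
    arcs: np.ndarray,
    total: float,
    spec: PhantomSpec,
    frame: int,
) -> np.ndarray:
    base = spec.segments[seg_index].base_width
    w = np.full(len(arcs), float(base))
    for les in spec.stenoses:
        if les.segment != seg_index:
            continue
        deg = lesion_degree(les, frame)
        s0 = les.position * total
        rel = arcs - s0
        inside = np.abs(rel) <= les.extent / 2.0
        dip = deg * (1.0 + np.cos(2.0 * np.pi * rel[inside] / les.extent)) / 2.0
        w[inside] *= 1.0 - dip
    return w


def _stamp(mask: np.ndarray, cx: float, cy: float, width: float) -> None:
    r = width / 2.0
    h, wd = mask.shape
    x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r))
    y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r))
    x0, x1 = max(0, x0), min(wd - 1, x1)
    y0, y1 = max(0, y0), min(h - 1, y1)
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    mask[y0 : y1 + 1, x0 : x1 + 1] |= (
        (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    )


def _frame_geometry(spec: PhantomSpec, frame: int):
    """Per-segment (samples, arcs, widths) for one frame, after motion."""
    dx = spec.motion_per_frame[0] * frame
    dy = spec.motion_per_frame[1] * frame
    geo = []
    for i, seg in enumerate(spec.segments):
        pts = [(x + dx, y + dy) for x, y in seg.points]
        samples, arcs = _sample_polyline(pts, step=0.5)
        widths = _segment_widths(i, arcs, float(arcs[-1]) if len(arcs) else 0.0,
                                 spec, frame)
        geo.append((samples, arcs, widths))
    return geo


def render_vessel_mask(spec: PhantomSpec, frame: int) -> np.ndarray:
    """Render the binary mask of one frame (uint8 grid of 0/1)."""
    validate_spec(spec)
    if not (0 <= frame < spec.n_frames):
        raise PhantomValidationError("frame must satisfy frame < n_frames")
    mask = np.zeros((spec.image_height, spec.image_width), dtype=bool)
    for samples, _, widths in _frame_geometry(spec, frame):
        for (cx, cy), w in zip(samples, widths):
            _stamp(mask, cx, cy, w)
    return mask.astype(np.uint8)


def make_sequence(spec: PhantomSpec) -> tuple[list[np.ndarray], PhantomTruth]:
    """Render all frames and assemble the ground-truth sidecar.

    Frame t is frame 0 rigidly translated by t * motion_per_frame with
    lesion widths modulated per frame.  A per-frame motion magnitude at
    or beyond the matching threshold (|dx|+|dy| >= 65) is rendered
    anyway but logged as a warning, since matching is then expected to
    fail by design.
    """
    validate_spec(spec)
    if abs(spec.motion_per_frame[0]) + abs(spec.motion_per_frame[1]) >= 65:
        logger.warning("per-frame motion magnitude >= 65 px: inter-frame "
                       "matching will fail by design")
    children: dict[int, list[int]] = {}
    for i, seg in enumerate(spec.segments):
        if seg.parent is not None:
            children.setdefault(seg.parent, []).append(i)
    masks: list[np.ndarray] = []
    frames: list[dict] = []
    h, w = spec.image_height, spec.image_width
    for t in range(spec.n_frames):
        masks.append(render_vessel_mask(spec, t))
        geo = _frame_geometry(spec, t)
        seg_records = []
        for i, (samples, arcs, widths) in enumerate(geo):
            inside = (
                (samples[:, 0] >= 0) & (samples[:, 0] <= w - 1)
                & (samples[:, 1] >= 0) & (samples[:, 1] <= h - 1)
            )
            seg_records.append({
                "index": i,
                "correspondence_id": i,
                "parent": spec.segments[i].parent,
                "centerline": [[float(x), float(y)] for x, y in samples],
                "widths": [float(v) for v in widths],
                "clipped": bool(~inside.all()),
            })
        bifurcations = [
            [float(geo[p][0][-1, 0]), float(geo[p][0][-1, 1])]
            for p, kids in sorted(children.items()) if len(kids) >= 2
        ]
        endpoints = []
        for i, (samples, _, _) in enumerate(geo):
            if spec.segments[i].parent is None:
                endpoints.append([float(samples[0, 0]), float(samples[0, 1])])
            if len(children.get(i, [])) == 0:
                endpoints.append([float(samples[-1, 0]), float(samples[-1, 1])])
        lesion_records = [
            {"index": j, "segment": les.segment,
             "degree": lesion_degree(les, t), "bridge": bool(les.periodic)}
            for j, les in enumerate(spec.stenoses)
        ]
        frames.append({
            "frame_index": t,
            "segments": seg_records,
            "bifurcations": bifurcations,
            "endpoints": endpoints,
            "lesions": lesion_records,
        })
    lesions = [
        {"segment": les.segment, "position": les.position,
         "severity": les.severity, "extent": les.extent,
         "periodic": bool(les.periodic), "period_frames": les.period_frames,
         "bridge": bool(les.periodic)}
        for les in spec.stenoses
    ]
    truth = PhantomTruth(image_height=h, image_width=w, n_frames=spec.n_frames,
                         frames=frames, lesions=lesions)
    validate_truth(truth.to_dict())
    return masks, truth


def write_phantom(dir_path: str, masks: list[np.ndarray], truth: PhantomTruth) -> list[str]:
    """Write masks as 8-bit 0/255 PNGs (frame_%04d.png) plus truth.json.

    Returns the written file paths; round-trips bit-exactly through
    :func:`angiotrack.io_cli.read_mask_sequence`.
    """
    if not masks:
        raise ValueError("write_phantom: no frames to write")
    os.makedirs(dir_path, exist_ok=True)
    written = []
    for t, m in enumerate(masks):
        path = os.path.join(dir_path, f"frame_{t:04d}.png")
        iio.imwrite(path, ((np.asarray(m) > 0) * 255).astype(np.uint8))
        written.append(path)
    tpath = os.path.join(dir_path, "truth.json")
    with open(tpath, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    written.append(tpath)
    return written


# ---------------------------------------------------------------------------
# layout helpers used by the tests and the acceptance suite
# ---------------------------------------------------------------------------

def straight_vessel_spec(
    width: float = 5.0,
    angle_deg: float = 0.0,
    length: float = 100.0,
    image_size: int = 160,
) -> PhantomSpec:
    """A single straight vessel through the image center at a given angle."""
    c = float(image_size // 2)
    ux, uy = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    p0 = (c - ux * length / 2, c - uy * length / 2)
    p1 = (c + ux * length / 2, c + uy * length / 2)
    return PhantomSpec(
        image_height=image_size, image_width=image_size,
        segments=[CenterlineSpec(points=[p0, p1], base_width=width)],
    )


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return math.inf
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def random_tree_spec(
    seed: int,
    n_segments: int = 5,
    image_size: int = 256,
    n_frames: int = 1,
    motion_per_frame: tuple[float, float] = (0.0, 0.0),
    margin: float = 18.0,
) -> PhantomSpec:
    """A seeded random branching layout that honours the pipeline's
    anatomy: a catheter-proximal root near the upper-left corner, only
    bi-/trifurcations (a junction with a single continuing child is the
    same vessel, not a branch), no overlapping of non-adjacent vessels,
    and everything inside the image for every frame of the motion.

    ``n_segments`` must be expressible as 1 + 2a + 3b (1, 3, 4, 5, ...).
    """
    rng = np.random.default_rng(seed)
    reach_x = abs(motion_per_frame[0]) * (n_frames - 1)
    reach_y = abs(motion_per_frame[1]) * (n_frames - 1)
    lo_x = margin + max(0.0, -motion_per_frame[0] * (n_frames - 1))
    lo_y = margin + max(0.0, -motion_per_frame[1] * (n_frames - 1))
    hi_x = image_size - 1 - margin - max(0.0, reach_x if motion_per_frame[0] > 0 else 0.0)
    hi_y = image_size - 1 - margin - max(0.0, reach_y if motion_per_frame[1] > 0 else 0.0)

    for attempt in range(300):
        segs: list[CenterlineSpec] = []
        samples: list[np.ndarray] = []
        angles: list[float] = []
        child_count: dict[int, int] = {}
        start = (lo_x + rng.uniform(0, 12), lo_y + rng.uniform(0, 12))
        ang = _safe_angle(rng.uniform(math.radians(20), math.radians(70)))
        length = rng.uniform(35, 60)
        width = rng.uniform(6, 9)
        end = (start[0] + length * math.cos(ang), start[1] + length * math.sin(ang))
        segs.append(CenterlineSpec(points=[start, end], base_width=width))
        samples.append(_sample_polyline([start, end])[0])
        angles.append(ang)
        ok = _in_bounds(samples[0], lo_x, hi_x, lo_y, hi_y)

        while ok and len(segs) < n_segments:
            remaining = n_segments - len(segs)
            open_parents = [i for i in range(len(segs)) if child_count.get(i, 0) == 0]
            if not open_parents or remaining < 2:
                ok = False
                break
            parent = int(rng.choice(open_parents))
            n_kids = 3 if (remaining >= 3 and rng.random() < 0.3) else 2
            n_kids = min(n_kids, remaining)
            if n_kids < 2:
                ok = False
                break
            base = angles[parent]
            deltas = _branch_deltas(rng, n_kids)
            placed = []
            for delta in deltas:
                a = _safe_angle(base + delta)
                length = rng.uniform(26, 48)
                w = max(3.0, segs[parent].base_width * rng.uniform(0.6, 0.8))
                p0 = tuple(np.asarray(segs[parent].points[-1], dtype=float))
                p1 = (p0[0] + length * math.cos(a), p0[1] + length * math.sin(a))
                cand = CenterlineSpec(points=[p0, p1], base_width=w, parent=parent)
                cs = _sample_polyline([p0, p1])[0]
                if not _in_bounds(cs, lo_x, hi_x, lo_y, hi_y):
                    break
                if not _clear_of_others(cs, w, segs, samples, parent, placed, p0):
                    break
                placed.append((cand, cs, a))
            if len(placed) < n_kids:
                ok = False
                break
            for cand, cs, a in placed:
                child_count[parent] = child_count.get(parent, 0) + 1
                segs.append(cand)
                samples.append(cs)
                angles.append(a)
        if ok and len(segs) == n_segments:
            return PhantomSpec(
                image_height=image_size, image_width=image_size,
                seed=seed, segments=segs, motion_per_frame=motion_per_frame,
                n_frames=n_frames,
            )
    raise RuntimeError(f"random_tree_spec: no valid layout found for seed {seed}")


def _in_bounds(samples: np.ndarray, lo_x, hi_x, lo_y, hi_y) -> bool:
    return bool(
        (samples[:, 0] >= lo_x).all() and (samples[:, 0] <= hi_x).all()
        and (samples[:, 1] >= lo_y).all() and (samples[:, 1] <= hi_y).all()
    )


def _safe_angle(a: float) -> float:
    """Nudge a direction away from exact diagonals.

    Two-subiteration thinning has a known degeneracy: a perfectly
    straight band running at exactly 45 degrees can, at unlucky
    sub-pixel phases, erode away entirely.  Real vessels are never
    ideal diagonals, so the layout helper simply avoids directions
    within 4 degrees of a diagonal.
    """
    deg = math.degrees(a)
    rel = (deg - 45.0) % 90.0
    if rel > 45.0:
        rel -= 90.0
    if abs(rel) < 4.0:
        deg += 4.0 - rel if rel >= 0 else -(4.0 + rel)
    return math.radians(deg)


def _branch_deltas(rng: np.random.Generator, n_kids: int) -> list[float]:
    """Branch direction offsets with >= 35 degrees mutual separation."""
    if n_kids == 2:
        left = -rng.uniform(math.radians(25), math.radians(55))
        right = rng.uniform(math.radians(25), math.radians(55))
        return [left, right]
    return [-rng.uniform(math.radians(40), math.radians(60)),
            rng.uniform(math.radians(-8), math.radians(8)),
            rng.uniform(math.radians(40), math.radians(60))]


def _clear_of_others(
    cs: np.ndarray,
    w: float,
    segs: list[CenterlineSpec],
    samples: list[np.ndarray],
    parent: int,
    placed: list,
    junction: tuple[float, float],
) -> bool:
    j = np.asarray(junction)
    for i, (other, os_) in enumerate(zip(segs, samples)):
        clearance = w / 2 + other.base_width / 2 + 3.0
        if i == parent:
            r = w + other.base_width
            keep_c = cs[np.hypot(cs[:, 0] - j[0], cs[:, 1] - j[1]) > r]
            keep_o = os_[np.hypot(os_[:, 0] - j[0], os_[:, 1] - j[1]) > r]
            if _min_dist(keep_c, keep_o) < clearance:
                return False
        else:
            if _min_dist(cs, os_) < clearance:
                return False
    for sib, ss, _ in placed:
        clearance = w / 2 + sib.base_width / 2 + 3.0
        r = w + sib.base_width
        keep_c = cs[np.hypot(cs[:, 0] - j[0], cs[:, 1] - j[1]) > r]
        keep_s = ss[np.hypot(ss[:, 0] - j[0], ss[:, 1] - j[1]) > r]
        if _min_dist(keep_c, keep_s) < clearance:
            return False
    return True


def lesion_sequence_spec(
    seed: int,
    periodic: bool,
    n_frames: int = 12,
    image_size: int = 256,
) -> PhantomSpec:
    """A seeded sequence with one lesioned proximal vessel: the phantom
    of a myocardial-bridge study case (``periodic=True``) or of a fixed
    focal stenosis (``periodic=False``).

    The lesioned root carries two distal children so it is non-
    peripheral; the whole tree drifts rigidly by a small per-frame
    translation, as between adjacent angiography frames.
    """
    rng = np.random.default_rng(seed)
    start = (30.0 + rng.uniform(0, 8), 30.0 + rng.uniform(0, 8))
    ang = _safe_angle(rng.uniform(math.radians(30), math.radians(55)))
    length = rng.uniform(85, 105)
    width = rng.uniform(8, 10)
    end = (start[0] + length * math.cos(ang), start[1] + length * math.sin(ang))
    root = CenterlineSpec(points=[start, end], base_width=width)
    kids = []
    for delta in (-rng.uniform(math.radians(30), math.radians(45)),
                  rng.uniform(math.radians(30), math.radians(45))):
        a = _safe_angle(ang + delta)
        ln = rng.uniform(30, 42)
        kids.append(CenterlineSpec(
            points=[end, (end[0] + ln * math.cos(a), end[1] + ln * math.sin(a))],
            base_width=max(3.0, width * rng.uniform(0.55, 0.7)),
            parent=0,
        ))
    severity = rng.uniform(0.45, 0.6) if periodic else rng.uniform(0.35, 0.5)
    lesion = LesionSpec(
        segment=0,
        position=rng.uniform(0.40, 0.55),
        severity=float(severity),
        extent=rng.uniform(18, 26),
        periodic=periodic,
        period_frames=6,
    )
    motion = (float(rng.integers(1, 4)), float(rng.integers(1, 3)))
    return PhantomSpec(
        image_height=image_size, image_width=image_size, seed=seed,
        segments=[root] + kids, motion_per_frame=motion,
        n_frames=n_frames, stenoses=[lesion],
    )
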