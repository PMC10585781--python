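"""Inter-frame vessel matching and sequence-wide track building.

Between heartbeats a vessel translates and folds but its topology and
length barely change, so two segments in different frames are matched on
their start points, end points and lengths:

    d_s  = |x_s1 - x_s2| + |y_s1 - y_s2|
    d_e  = |x_e1 - x_e2| + |y_e1 - y_e2|
    rate = min(L1, L2) / max(L1, L2)

and accepted when d_s < 65, d_e < 65 and rate > 0.80 (strict, as
thresholds tied to the acquisition frame rate).  When several candidate
pairs share a segment, the pair with the smallest d_s + d_e wins.  To
survive frames where a vessel is briefly invisible, unmatched segments
are also tried against the second and third following frames; a segment
already linked into a track is never re-matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from angiotrack.config import PipelineConfig
from angiotrack.segments import VesselSegment

logger = logging.getLogger("angiotrack.fusion")


@dataclass(frozen=True)
class MatchRecord:
    frame_a: int
    id_a: int
    frame_b: int
    id_b: int
    d_s: float
    d_e: float
    rate: float


@dataclass
class VesselTrack:
    """The same physical vessel linked across frames."""

    track_id: int
    members: list[tuple[int, int]] = field(default_factory=list)  # (frame, id)
    #: per-frame most-severe stenosis degree, fraction in [0, 1]
    stenosis_degree: dict[int, float] = field(default_factory=dict)
    #: per-frame mean vessel diameter, px
    mean_diameter: dict[int, float] = field(default_factory=dict)

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.members]


def match_pair(
    seg_a: VesselSegment,
    seg_b: VesselSegment,
    config: PipelineConfig | None = None,
) -> MatchRecord | None:
    """Match two segments from different frames, or return None."""
    cfg = config or PipelineConfig()
    if seg_a.length == 0 or seg_b.length == 0:
        raise ValueError("cannot match a zero-length segment")
    d_s = abs(seg_a.start[0] - seg_b.start[0]) + abs(seg_a.start[1] - seg_b.start[1])
    d_e = abs(seg_a.end[0] - seg_b.end[0]) + abs(seg_a.end[1] - seg_b.end[1])
    rate = min(seg_a.length, seg_b.length) / max(seg_a.length, seg_b.length)
    if d_s < cfg.d_s_max and d_e < cfg.d_e_max and rate > cfg.rate_min:
        return MatchRecord(seg_a.frame_index, seg_a.id, seg_b.frame_index, seg_b.id,
                           float(d_s), float(d_e), float(rate))
    return None


def match_frames(
    frame_a_segs: list[VesselSegment],
    frame_b_segs: list[VesselSegment],
    config: PipelineConfig | None = None,
) -> list[MatchRecord]:
    """One-to-one matching between two frames.

    All pairs passing the thresholds are collected, then assigned
    greedily in ascending d_s + d_e (ties: smaller ids), so each segment
    is matched at most once and ambiguities resolve to the spatially
    closest pair independent of input order.
    """
    cfg = config or PipelineConfig()
    candidates: list[MatchRecord] = []
    for a in frame_a_segs:
        for b in frame_b_segs:
            rec = match_pair(a, b, cfg)
            if rec is not None:
                candidates.append(rec)
    candidates.sort(key=lambda r: (r.d_s + r.d_e, r.id_a, r.id_b))
    used_a: set[int] = set()
    used_b: set[int] = set()
    accepted = []
    for rec in candidates:
        if rec.id_a in used_a or rec.id_b in used_b:
            continue
        used_a.add(rec.id_a)
        used_b.add(rec.id_b)
        accepted.append(rec)
    return accepted


def fuse_sequence(
    frames: list[list[VesselSegment]],
    config: PipelineConfig | None = None,
    max_gap: int = 3,
) -> tuple[list[VesselTrack], list[MatchRecord]]:
    """Link segments across a sequence into vessel tracks.

    Every segment opens a track when first seen; for each frame t the
    tracks ending at t try to extend into frame t+1, then t+2, then
    t+3.  Returns the tracks (frame-sorted members) and all accepted
    match records.  The segments' ``track_id`` attribute is set.
    """
    cfg = config or PipelineConfig()
    if len(frames) < 2:
        raise ValueError("fuse_sequence needs at least 2 frames")
    track_of: dict[tuple[int, int], VesselTrack] = {}
    tracks: list[VesselTrack] = []
    matches: list[MatchRecord] = []

    for t, segs in enumerate(frames):
        for s in segs:
            if (t, s.id) not in track_of:
                tr = VesselTrack(track_id=len(tracks), members=[(t, s.id)])
                tracks.append(tr)
                track_of[(t, s.id)] = tr
                s.track_id = tr.track_id
        for gap in range(1, max_gap + 1):
            tb = t + gap
            if tb >= len(frames):
                break
            # only tracks whose tail is still at frame t keep looking
            a_pool = [s for s in segs
                      if track_of[(t, s.id)].members[-1] == (t, s.id)]
            b_pool = [s for s in frames[tb] if (tb, s.id) not in track_of]
            if not a_pool or not b_pool:
                continue
            for rec in match_frames(a_pool, b_pool, cfg):
                tr = track_of[(t, rec.id_a)]
                tr.members.append((tb, rec.id_b))
                track_of[(tb, rec.id_b)] = tr
                matches.append(rec)
                seg_b = next(s for s in frames[tb] if s.id == rec.id_b)
                seg_b.track_id = tr.track_id
    for tr in tracks:
        tr.members.sort()
    logger.info("fused %d frames into %d tracks (%d matches)",
                len(frames), len(tracks), len(matches))
    return tracks, matches
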