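"""End-to-end analysis: masks in, sequence report out.

Per frame: thinning -> staircase smoothing -> keypoints -> path
splitting -> burr removal -> skeleton repair -> re-splitting -> segment
description -> vessel tree.  Per sequence: inter-frame matching into
tracks, stenosis quantification per segment, myocardial-bridge screening
per track.  The result is a plain JSON-serializable report.
"""

from __future__ import annotations

import csv
import dataclasses
import logging

import numpy as np

from angiotrack import clinical, fusion, skeleton as sk, tree as treemod
from angiotrack.config import PipelineConfig
from angiotrack.io_cli import validate_report, write_report  # noqa: F401 (re-export)
from angiotrack.segments import DiameterProfile, VesselSegment, describe

logger = logging.getLogger("angiotrack.pipeline")


@dataclasses.dataclass
class FrameResult:
    frame_index: int
    skeleton: np.ndarray
    keypoints: sk.KeyPointSet
    segments: list[VesselSegment]
    tree: treemod.VesselTree | None
    smoothed: dict[int, DiameterProfile]


def analyze_frame(
    mask: np.ndarray, frame_index: int = 0, config: PipelineConfig | None = None
) -> FrameResult:
    """Run the single-frame stages on one binary mask."""
    cfg = config or PipelineConfig()
    skel = sk.remove_staircase(sk.thin(mask))
    kps = sk.detect_keypoints(skel)
    paths = sk.split_segments(skel, kps, frame_index)
    kept = sk.remove_burrs(paths, cfg.burr_min_len)
    kept_ids = {id(p) for p in kept}
    removed = [p for p in paths if id(p) not in kept_ids]
    if removed:
        logger.info("frame %d: removed %d burr paths", frame_index, len(removed))
    deburred = sk.deburred_skeleton(skel, removed)
    repaired = sk.repair(skel, deburred)
    kps2 = sk.detect_keypoints(repaired)
    paths2 = sk.remove_burrs(sk.split_segments(repaired, kps2, frame_index),
                             cfg.burr_min_len)
    segments = describe(mask, paths2, kps2.intersections, cfg, skip_failed=True)
    tr = treemod.build_tree(segments, cfg.d_n_threshold) if segments else None
    smoothed: dict[int, DiameterProfile] = {}
    for seg in segments:
        n_w = min(cfg.smooth_N_w, len(seg.profile))
        if n_w % 2 == 0:
            n_w -= 1
        smoothed[seg.id] = clinical.smooth_profile(seg.profile, max(1, n_w))
    return FrameResult(frame_index=frame_index, skeleton=repaired, keypoints=kps2,
                       segments=segments, tree=tr, smoothed=smoothed)


def _frame_degree(
    frame: FrameResult, seg: VesselSegment, cfg: PipelineConfig
) -> float | None:
    """Most-severe stenosis degree (fraction) of a segment, 0.0 when the
    vessel has no stenosis candidate, None when it cannot be assessed."""
    prof = frame.smoothed[seg.id]
    if len(prof) < 5:
        return None
    cands = clinical.stenosis_candidates(
        prof, peripheral=seg.peripheral, path_length=len(seg.path.pixels),
        config=cfg, frame_index=frame.frame_index, segment_id=seg.id)
    if not cands:
        return 0.0
    return max(c.percent for c in cands) / 100.0


def run_pipeline(
    masks: list[np.ndarray], config: PipelineConfig | None = None
) -> dict:
    """Analyze a mask sequence and return the JSON-serializable report.

    A frame whose skeletonization fails is skipped with a logged error;
    the sequence continues.  Deterministic for fixed input and config.
    """
    cfg = config or PipelineConfig()
    if not masks:
        raise ValueError("run_pipeline: need at least one frame")
    frames: list[FrameResult] = []
    for t, mask in enumerate(masks):
        try:
            frames.append(analyze_frame(mask, t, cfg))
        except Exception:
            logger.exception("frame %d failed; skipping", t)
            frames.append(FrameResult(t, np.zeros_like(np.asarray(mask)),
                                      sk.KeyPointSet([], []), [], None, {}))

    stenoses: list[clinical.StenosisFinding] = []
    for fr in frames:
        for seg in fr.segments:
            prof = fr.smoothed[seg.id]
            if len(prof) < 5:
                continue
            stenoses.extend(clinical.quantify_stenosis(
                prof, peripheral=seg.peripheral,
                path_length=len(seg.path.pixels), config=cfg,
                frame_index=fr.frame_index, segment_id=seg.id))

    tracks: list[fusion.VesselTrack] = []
    matches: list[fusion.MatchRecord] = []
    bridges: list[clinical.BridgeFinding] = []
    if len(frames) >= 2:
        tracks, matches = fusion.fuse_sequence([fr.segments for fr in frames], cfg)
        seg_by = {(fr.frame_index, s.id): (fr, s)
                  for fr in frames for s in fr.segments}
        for tr in tracks:
            for f, sid in tr.members:
                frame, seg = seg_by[(f, sid)]
                tr.stenosis_degree[f] = _frame_degree(frame, seg, cfg)
                prof = frame.smoothed[seg.id]
                tr.mean_diameter[f] = float(np.mean(prof.values)) if len(prof) else None
            finding = clinical.detect_bridge(tr, cfg)
            if finding is not None:
                bridges.append(finding)

    return _build_report(frames, matches, tracks, stenoses, bridges, cfg)


def _build_report(frames, matches, tracks, stenoses, bridges, cfg) -> dict:
    from angiotrack import __version__

    report = {
        "metadata": {
            "version": __version__,
            "config": cfg.to_dict(),
            "n_frames": len(frames),
        },
        "frames": [],
        "matches": [dataclasses.asdict(m) for m in matches],
        "tracks": [
            {"track_id": tr.track_id,
             "members": [list(m) for m in tr.members],
             "stenosis_degree": {str(f): d for f, d in tr.stenosis_degree.items()},
             "mean_diameter": {str(f): d for f, d in tr.mean_diameter.items()}}
            for tr in tracks
        ],
        "stenoses": [dataclasses.asdict(s) for s in stenoses],
        "bridges": [dataclasses.asdict(b) for b in bridges],
    }
    for fr in frames:
        frec = {
            "frame_index": fr.frame_index,
            "segments": [
                {"id": s.id, "start": list(s.start), "end": list(s.end),
                 "length": s.length, "mean_diameter": s.mean_diameter,
                 "parent": s.parent, "children": list(s.children),
                 "track_id": s.track_id}
                for s in fr.segments
            ],
            "keypoints": {
                "endpoints": [list(p) for p in fr.keypoints.endpoints],
                "intersections": [list(p) for p in fr.keypoints.intersections],
            },
            "tree": None if fr.tree is None else {
                "roots": list(fr.tree.roots),
                "nodes": [
                    {"id": nid, "parent": node.parent,
                     "children": list(node.children)}
                    for nid, node in sorted(fr.tree.nodes.items())
                ],
            },
        }
        report["frames"].append(frec)
    validate_report(report)
    return report


def export_profiles_csv(frames: list[FrameResult], path: str) -> None:
    """Write every diameter sample as CSV:
    frame, segment_id, path_index, x, y, diameter_px."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "segment_id", "path_index", "x", "y", "diameter_px"])
        for fr in frames:
            for seg in fr.segments:
                for pos, val in zip(seg.profile.positions, seg.profile.values):
                    x, y = seg.path.pixels[int(pos)]
                    w.writerow([fr.frame_index, seg.id, int(pos), x, y,
                                f"{val:.3f}"])


def export_tracks_csv(report: dict, path: str) -> None:
    """Per-track per-frame stenosis degree and mean diameter as CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["track_id", "frame", "stenosis_degree", "mean_diameter_px"])
        for tr in report["tracks"]:
            for f, _ in tr["members"]:
                w.writerow([tr["track_id"], f,
                            tr["stenosis_degree"].get(str(f)),
                            tr["mean_diameter"].get(str(f))])
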