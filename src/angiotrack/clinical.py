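"""Stenosis quantification/grading and myocardial-bridge detection.

A vessel's diameter curve is first smoothed with a trailing moving
average.  A stenosis candidate is a local minimum of the curve; the
expected healthy diameter is the mean of the nearest local maxima on
either side (D_f, D_b), giving the percent diameter stenosis

    P = (1 - 2 * D_min / (D_f + D_b)) * 100.

Grading follows clinical practice: mild 30–50 % (label 0), moderate
50–70 % (label 1), severe over 70 % (label 2); anything below 30 % is a
normal vessel.

A myocardial bridge shows as the "milking effect": periodic narrowing
of the same vessel across the sequence.  Over a vessel track it is
called when either rule fires (checked in this order):

  A. max - min of the per-frame stenosis degree >= 0.25, with the two
     extreme frames at least 3 frames apart;
  B. min / max of the per-frame mean diameter <= 0.75, again with the
     extreme frames at least 3 frames apart (covers long lesions whose
     stenosis degree cannot be measured).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from angiotrack.config import PipelineConfig
from angiotrack.segments import DiameterProfile
from angiotrack.fusion import VesselTrack

logger = logging.getLogger("angiotrack.clinical")

GRADE_NORMAL = "normal"


@dataclass(frozen=True)
class StenosisFinding:
    frame_index: int
    segment_id: int
    position: int          # path index of the minimum
    d_min: float
    d_f: float
    d_b: float
    percent: float
    grade: str | int


@dataclass(frozen=True)
class BridgeFinding:
    track_id: int
    rule: str              # "stenosis_variation" or "diameter_ratio"
    stenosis_max: float | None = None
    stenosis_min: float | None = None
    stenosis_max_frame: int | None = None
    stenosis_min_frame: int | None = None
    average_max: float | None = None
    average_min: float | None = None
    average_max_frame: int | None = None
    average_min_frame: int | None = None


def smooth_profile(profile: DiameterProfile, n_w: int = 5) -> DiameterProfile:
    """Trailing moving average y(k) = mean of x(k-N_w+1 .. k).

    Near the left edge the window shrinks to the available samples.
    ``n_w`` must be odd, >= 1 and no longer than the profile.
    """
    if n_w < 1 or n_w % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if n_w > len(profile):
        raise ValueError("smoothing window longer than the profile")
    x = profile.values
    c = np.concatenate([[0.0], np.cumsum(x)])
    k = np.arange(len(x))
    lo = np.maximum(0, k - n_w + 1)
    y = (c[k + 1] - c[lo]) / (k + 1 - lo)
    return DiameterProfile(values=y, positions=profile.positions.copy())


def _run_collapsed(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse equal-value runs; return (run start indices, run values)."""
    keep = np.concatenate([[True], np.diff(values) != 0])
    return np.nonzero(keep)[0], values[keep]


def _local_extrema(values: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of interior local minima and maxima (plateaus collapsed,
    represented by the first index of the run)."""
    idx, v = _run_collapsed(values)
    minima, maxima = [], []
    for j in range(1, len(v) - 1):
        if v[j] < v[j - 1] and v[j] < v[j + 1]:
            minima.append(int(idx[j]))
        elif v[j] > v[j - 1] and v[j] > v[j + 1]:
            maxima.append(int(idx[j]))
    return minima, maxima


def grade(p: float) -> str | int:
    """Clinical stenosis grade for a percent stenosis P."""
    if p >= 70.0:
        return 2
    if p >= 50.0:
        return 1
    if p >= 30.0:
        return 0
    return GRADE_NORMAL


def _flank_maxima(values: np.ndarray, maxima: list[int], i: int) -> tuple[float, float]:
    """Nearest local maxima left and right of index i; a profile
    endpoint counts as a maximum when the curve runs monotonically
    into it."""
    left = [m for m in maxima if m < i]
    right = [m for m in maxima if m > i]
    d_f = values[left[-1]] if left else values[0]
    d_b = values[right[0]] if right else values[-1]
    return float(d_f), float(d_b)


def stenosis_candidates(
    profile: DiameterProfile,
    peripheral: bool = False,
    path_length: int | None = None,
    config: PipelineConfig | None = None,
    frame_index: int = 0,
    segment_id: int = 0,
) -> list[StenosisFinding]:
    """All stenosis candidates of a (smoothed) profile, ungraded by any
    reporting floor.

    Non-peripheral vessels: the single candidate is the global minimum
    of the whole diameter curve (skipped when it sits on the profile
    boundary, i.e. the curve is monotone).  Peripheral (leaf) vessels:
    every interior local minimum outside the distal 20 % of the path.
    """
    cfg = config or PipelineConfig()
    v = profile.values
    if len(v) < 5:
        return []
    minima, maxima = _local_extrema(v)
    if peripheral:
        limit = (1.0 - cfg.peripheral_distal_exclusion) * (
            path_length - 1 if path_length else profile.positions[-1]
        )
        cand = [m for m in minima if profile.positions[m] <= limit]
    else:
        g = int(np.argmin(v))
        if g in (0, len(v) - 1):
            # re-anchor to the first interior minimum run if the raw
            # argmin lies on a boundary plateau
            cand = [minima[int(np.argmin(v[minima]))]] if minima else []
        else:
            cand = [g]
    out = []
    for m in cand:
        d_min = float(v[m])
        d_f, d_b = _flank_maxima(v, maxima, m)
        if d_f + d_b <= 0:
            continue
        p = (1.0 - 2.0 * d_min / (d_f + d_b)) * 100.0
        p = max(p, 0.0)
        out.append(StenosisFinding(
            frame_index=frame_index, segment_id=segment_id,
            position=int(profile.positions[m]),
            d_min=d_min, d_f=d_f, d_b=d_b, percent=p, grade=grade(p)))
    return out


def quantify_stenosis(
    profile: DiameterProfile,
    peripheral: bool = False,
    path_length: int | None = None,
    config: PipelineConfig | None = None,
    frame_index: int = 0,
    segment_id: int = 0,
) -> list[StenosisFinding]:
    """Reportable stenosis findings of a smoothed profile: candidates at
    or above the reporting floor (30 % by default); milder candidates
    are normal vessels and discarded."""
    cfg = config or PipelineConfig()
    return [f for f in stenosis_candidates(
        profile, peripheral, path_length, cfg, frame_index, segment_id)
        if f.percent >= cfg.stenosis_report_floor]


def detect_bridge(
    track: VesselTrack, config: PipelineConfig | None = None
) -> BridgeFinding | None:
    """Screen one vessel track for a myocardial bridge.

    Requires >= 4 members and the per-frame summaries
    (``track.stenosis_degree``, ``track.mean_diameter``) to be filled.
    Rule A (stenosis variation) is checked before rule B (diameter
    ratio).  A rule fires when *some* pair of frames at least
    ``bridge_frame_gap`` apart shows the required swing (or ratio); the
    reported extrema are the qualifying pair with the largest swing
    (smallest ratio), so near-equal periodic extremes cannot defeat the
    frame-gap requirement.
    """
    cfg = config or PipelineConfig()
    if len(track.members) < 4:
        logger.debug("track %d too short for bridge detection", track.track_id)
        return None
    deg = {f: d for f, d in sorted(track.stenosis_degree.items()) if d is not None}
    best = None  # (swing, f_max, f_min)
    for f_hi, v_hi in deg.items():
        for f_lo, v_lo in deg.items():
            if abs(f_hi - f_lo) < cfg.bridge_frame_gap:
                continue
            swing = v_hi - v_lo
            if swing >= cfg.bridge_stenosis_delta and (
                    best is None or swing > best[0]):
                best = (swing, f_hi, f_lo)
    if best is not None:
        _, f_max, f_min = best
        return BridgeFinding(
            track_id=track.track_id, rule="stenosis_variation",
            stenosis_max=float(deg[f_max]), stenosis_min=float(deg[f_min]),
            stenosis_max_frame=f_max, stenosis_min_frame=f_min)
    dia = {f: d for f, d in sorted(track.mean_diameter.items()) if d is not None}
    best = None  # (ratio, f_max, f_min)
    for f_hi, v_hi in dia.items():
        for f_lo, v_lo in dia.items():
            if abs(f_hi - f_lo) < cfg.bridge_frame_gap or v_hi <= 0:
                continue
            ratio = v_lo / v_hi
            if ratio <= cfg.bridge_diameter_ratio and (
                    best is None or ratio < best[0]):
                best = (ratio, f_hi, f_lo)
    if best is not None:
        _, f_max, f_min = best
        return BridgeFinding(
            track_id=track.track_id, rule="diameter_ratio",
            average_max=float(dia[f_max]), average_min=float(dia[f_min]),
            average_max_frame=f_max, average_min_frame=f_min)
    return None
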