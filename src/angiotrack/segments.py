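"""Per-vessel description: diameter profile, length, start/end.

The diameter at a centerline pixel is measured along the normal of a
local least-squares line fitted to a short window of skeleton pixels
(window length N = 5 by default, truncated near the path ends).  From
the centerline pixel the normal is marched in both directions with
sub-pixel steps and bilinear mask interpolation until the mask is left;
the diameter is the Euclidean distance between the two exit points A
and B:

    d = sqrt((x_a - x_b)^2 + (y_a - y_b)^2).

Lengths are skeleton pixel counts; the start and end coordinates are the
two terminal skeleton pixels, oriented so the start is the endpoint
closer (city-block) to the image origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from angiotrack.config import PipelineConfig
from angiotrack.skeleton import CenterlinePath

logger = logging.getLogger("angiotrack.segments")


class ProfileError(ValueError):
    """Raised when no diameter sample of a segment can be measured."""


@dataclass(frozen=True)
class LineFit:
    """Least-squares line through a window of centerline pixels.

    For ``axis_swapped=False`` the line is y = a*x + b (minimizing
    vertical residuals); for near-vertical windows the fit is redone
    with the axes exchanged, so the line is x = a*y + b.
    """

    a: float
    b: float
    axis_swapped: bool = False

    def normal(self) -> tuple[float, float]:
        """Unit vector perpendicular to the fitted line, as (nx, ny)."""
        if self.axis_swapped:
            tx, ty = self.a, 1.0
        else:
            tx, ty = 1.0, self.a
        norm = float(np.hypot(tx, ty))
        return (-ty / norm, tx / norm)


@dataclass
class DiameterProfile:
    """Diameter samples (pixels) along a centerline path."""

    values: np.ndarray          # diameters, > 0
    positions: np.ndarray       # matching path indices

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.values.shape != self.positions.shape:
            raise ValueError("values and positions must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class VesselSegment:
    """One separated vessel with its descriptive attributes."""

    id: int
    frame_index: int
    path: CenterlinePath
    start: tuple[int, int]
    end: tuple[int, int]
    length: int
    profile: DiameterProfile
    track_id: int | None = None
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    @property
    def peripheral(self) -> bool:
        """Leaf vessels of the tree are peripheral (distal) vessels."""
        return not self.children

    def reverse_in_place(self) -> None:
        """Flip the segment's flow direction (start <-> end)."""
        n = len(self.path.pixels)
        self.path = self.path.reversed()
        self.start, self.end = self.end, self.start
        pos = n - 1 - self.profile.positions[::-1]
        vals = self.profile.values[::-1]
        self.profile = DiameterProfile(values=vals.copy(), positions=pos.copy())

    @property
    def mean_diameter(self) -> float:
        return float(np.mean(self.profile.values)) if len(self.profile) else float("nan")


def fit_local_line(points: list[tuple[float, float]]) -> LineFit:
    """Fit y = a*x + b to 2–5 (x, y) points by least squares.

    If the x spread is below 1e-6 the window is (numerically) vertical
    and the fit is redone with axes swapped.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2 or len(np.unique(pts, axis=0)) < 2:
        raise ValueError("need at least 2 distinct points for a line fit")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) < 1e-6:
        a, b = _lsq(y, x)
        return LineFit(a=a, b=b, axis_swapped=True)
    a, b = _lsq(x, y)
    return LineFit(a=a, b=b, axis_swapped=False)


def _lsq(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    denom = n * sxx - sx * sx
    if denom == 0:
        return 0.0, float(y.mean())
    a = (n * sxy - sx * sy) / denom
    b = (sy - a * sx) / n
    return float(a), float(b)


def _window(path: CenterlinePath, index: int, n: int) -> list[tuple[int, int]]:
    half = n // 2
    lo = max(0, index - half)
    hi = min(len(path.pixels), index + half + 1)
    return path.pixels[lo:hi]


def _march_exit(
    mask_f: np.ndarray,
    origin: tuple[float, float],
    direction: tuple[float, float],
    cap: float,
    step: float = 0.25,
) -> float | None:
    """Distance from ``origin`` to the sub-pixel 0.5-crossing of the
    interpolated mask along ``direction``; None if it never exits
    within ``cap`` pixels."""
    n_steps = int(cap / step)
    s = np.arange(1, n_steps + 1) * step
    xs = origin[0] + s * direction[0]
    ys = origin[1] + s * direction[1]
    vals = ndimage.map_coordinates(mask_f, [ys, xs], order=1, mode="constant", cval=0.0)
    below = np.nonzero(vals < 0.5)[0]
    if below.size == 0:
        return None
    k = int(below[0])
    v1 = vals[k]
    v0 = mask_f[int(round(origin[1])), int(round(origin[0]))] if k == 0 else vals[k - 1]
    s1 = s[k]
    s0 = s1 - step if k > 0 else 0.0
    if v0 <= 0.5:            # already outside at the first sample
        return s0 if k > 0 else 0.0
    frac = (v0 - 0.5) / (v0 - v1)
    return float(s0 + frac * (s1 - s0))


def diameter_at(
    mask: np.ndarray,
    path: CenterlinePath,
    index: int,
    config: PipelineConfig | None = None,
) -> float | None:
    """Vessel diameter at one centerline pixel, or None if the normal
    never exits the mask within the search cap."""
    cfg = config or PipelineConfig()
    mask_f = (np.asarray(mask) > 0).astype(float)
    x0, y0 = path.pixels[index]
    fit = fit_local_line(_window(path, index, cfg.line_fit_N))
    nx, ny = fit.normal()
    d_pos = _march_exit(mask_f, (x0, y0), (nx, ny), cfg.normal_search_cap)
    d_neg = _march_exit(mask_f, (x0, y0), (-nx, -ny), cfg.normal_search_cap)
    if d_pos is None or d_neg is None:
        logger.debug("normal did not exit mask at path index %d", index)
        return None
    d = d_pos + d_neg
    return d if d > 0 else None


def profile_segment(
    mask: np.ndarray,
    path: CenterlinePath,
    intersections: list[tuple[int, int]] | None = None,
    config: PipelineConfig | None = None,
) -> DiameterProfile:
    """Diameter profile of one centerline path.

    Samples within ``junction_exclusion`` pixels (Euclidean) of an
    intersection keypoint are skipped — the two-edge diameter model does
    not hold at bifurcations.  A second, data-driven guard removes
    samples whose measured diameter exceeds twice their distance to the
    nearest junction: there the chord still spans the bifurcation blob
    and the value is not a lumen diameter.  Samples where the normal
    never exits the mask are dropped, positions preserved.  Raises
    :class:`ProfileError` when nothing can be measured.
    """
    cfg = config or PipelineConfig()
    mask_f = (np.asarray(mask) > 0).astype(float)
    pix = np.asarray(path.pixels, dtype=float)
    keep = np.ones(len(pix), dtype=bool)
    if intersections:
        inter = np.asarray(intersections, dtype=float)
        d2 = ((pix[:, None, :] - inter[None, :, :]) ** 2).sum(axis=2)
        keep &= d2.min(axis=1) > cfg.junction_exclusion ** 2
    indices = np.nonzero(keep)[0]
    if indices.size == 0:
        raise ProfileError("all centerline samples lie within the junction margin")
    # precompute normals per sample, then march all rays in one pass
    normals = np.empty((indices.size, 2))
    for j, i in enumerate(indices):
        fit = fit_local_line(_window(path, int(i), cfg.line_fit_N))
        normals[j] = fit.normal()
    step = 0.25
    n_steps = int(cfg.normal_search_cap / step)
    s = np.arange(1, n_steps + 1) * step
    origins = pix[indices]
    values, positions = [], []
    coords_x = origins[:, 0, None] + s[None, :] * normals[:, 0, None]
    coords_y = origins[:, 1, None] + s[None, :] * normals[:, 1, None]
    coords_x = np.concatenate([coords_x, origins[:, 0, None] - s[None, :] * normals[:, 0, None]], axis=1)
    coords_y = np.concatenate([coords_y, origins[:, 1, None] - s[None, :] * normals[:, 1, None]], axis=1)
    vals = ndimage.map_coordinates(
        mask_f, [coords_y.ravel(), coords_x.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(coords_x.shape)
    if intersections:
        inter = np.asarray(intersections, dtype=float)
        jdist = np.sqrt(
            ((origins[:, None, :] - inter[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
    else:
        jdist = np.full(indices.size, np.inf)
    for j, i in enumerate(indices):
        half = [_exit_from_samples(vals[j, :n_steps], s, step),
                _exit_from_samples(vals[j, n_steps:], s, step)]
        if half[0] is None or half[1] is None:
            continue
        d = half[0] + half[1]
        if d <= 0 or jdist[j] < d / 2.0 + 1.0:
            continue
        values.append(d)
        positions.append(int(i))
    if not values:
        raise ProfileError("no diameter sample of the segment could be measured")
    return DiameterProfile(values=np.array(values), positions=np.array(positions))


def _exit_from_samples(vals: np.ndarray, s: np.ndarray, step: float) -> float | None:
    below = np.nonzero(vals < 0.5)[0]
    if below.size == 0:
        return None
    k = int(below[0])
    v1 = vals[k]
    v0 = 1.0 if k == 0 else vals[k - 1]
    s1 = s[k]
    s0 = s1 - step if k > 0 else 0.0
    if v0 <= 0.5:
        return s0
    return float(s0 + (v0 - 0.5) / (v0 - v1) * (s1 - s0))


def canonical_orientation(path: CenterlinePath) -> CenterlinePath:
    """Orient a path so its start is the endpoint with the smaller
    city-block distance to the image origin (ties: smaller y, then x)."""
    if path.is_closed or len(path.pixels) < 2:
        return path
    (xs, ys), (xe, ye) = path.pixels[0], path.pixels[-1]
    key_s = (xs + ys, ys, xs)
    key_e = (xe + ye, ye, xe)
    return path.reversed() if key_e < key_s else path


def describe(
    mask: np.ndarray,
    paths: list[CenterlinePath],
    intersections: list[tuple[int, int]] | None = None,
    config: PipelineConfig | None = None,
    skip_failed: bool = False,
) -> list[VesselSegment]:
    """Build one :class:`VesselSegment` per centerline path.

    IDs are provisional (input order); the tree module reassigns them.
    With ``skip_failed`` unprofilable paths are dropped with a warning
    instead of raising.
    """
    cfg = config or PipelineConfig()
    # profile exclusion must cover every split point, including junction
    # clusters that fail the strict intersection conditions
    junction_pts = set(intersections or [])
    for p in paths:
        if p.junction_start:
            junction_pts.add(p.pixels[0])
        if p.junction_end:
            junction_pts.add(p.pixels[-1])
    exclude = sorted(junction_pts)
    out: list[VesselSegment] = []
    for i, raw in enumerate(paths):
        path = canonical_orientation(raw)
        try:
            prof = profile_segment(mask, path, exclude, cfg)
        except ProfileError:
            if skip_failed:
                logger.warning("segment %d skipped: no measurable diameter", i)
                continue
            raise
        out.append(VesselSegment(
            id=i,
            frame_index=path.frame_index,
            path=path,
            start=path.pixels[0],
            end=path.pixels[-1],
            length=path.n_own,
            profile=prof,
        ))
    return out
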