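import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# neighbor offsets (dy, dx) for p2..p9: p2 above, then clockwise
P_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def thin_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Naive per-pixel two-subiteration thinning; the independent oracle
    for the vectorized implementation."""
    img = (np.asarray(mask) > 0).astype(int)
    h, w = img.shape
    while True:
        changed = False
        for sub in (0, 1):
            to_del = []
            ys, xs = np.nonzero(img)
            for y, x in zip(ys.tolist(), xs.tolist()):
                p = [img[y + dy, x + dx] if 0 <= y + dy < h and 0 <= x + dx < w else 0
                     for dy, dx in P_OFFSETS]
                n = sum(p)
                if not (2 <= n <= 6):
                    continue
                s = sum(1 for i in range(8) if p[i] == 0 and p[(i + 1) % 8] == 1)
                if s != 1:
                    continue
                p2, _, p4, _, p6, _, p8, _ = p
                if sub == 0:
                    ok = p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0
                else:
                    ok = p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0
                if ok:
                    to_del.append((y, x))
            for y, x in to_del:
                img[y, x] = 0
            changed = changed or bool(to_del)
        if not changed:
            return img.astype(np.uint8)


def random_blob_mask(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """A small random mask of discs, rectangles and thick strokes."""
    m = np.zeros((size, size), np.uint8)
    for _ in range(int(rng.integers(2, 5))):
        kind = int(rng.integers(0, 3))
        if kind == 0:
            y, x = rng.integers(5, size - 5, 2)
            r = int(rng.integers(2, 8))
            yy, xx = np.mgrid[0:size, 0:size]
            m |= ((yy - y) ** 2 + (xx - x) ** 2 <= r * r).astype(np.uint8)
        elif kind == 1:
            y0, x0 = rng.integers(0, size - 14, 2)
            hgt, wd = rng.integers(3, 14, 2)
            m[y0:y0 + hgt, x0:x0 + wd] = 1
        else:
            y0, x0 = rng.integers(5, size - 5, 2)
            y1, x1 = rng.integers(5, size - 5, 2)
            for t in np.linspace(0, 1, 40):
                yy = int(round(y0 + (y1 - y0) * t))
                xx = int(round(x0 + (x1 - x0) * t))
                m[max(0, yy - 1):yy + 2, max(0, xx - 1):xx + 2] = 1
    return m


def grid_from_coords(coords, shape=None) -> np.ndarray:
    """Binary grid from (x, y) coordinates."""
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    if shape is None:
        shape = (max(ys) + 2, max(xs) + 2)
    g = np.zeros(shape, np.uint8)
    for x, y in coords:
        g[y, x] = 1
    return g


@pytest.fixture
def make_segment():
    """Factory for bare VesselSegments (geometry only), for the tree and
    matching units that do not need a mask."""
    from angiotrack.segments import VesselSegment, DiameterProfile
    from angiotrack.skeleton import CenterlinePath

    def _make(seg_id, start, end, length=None, frame_index=0, diameters=None):
        n = length if length is not None else 10
        xs = np.linspace(start[0], end[0], n)
        ys = np.linspace(start[1], end[1], n)
        path = CenterlinePath(pixels=[(int(round(x)), int(round(y)))
                                      for x, y in zip(xs, ys)],
                              frame_index=frame_index)
        path.pixels[0] = tuple(start)
        path.pixels[-1] = tuple(end)
        d = diameters if diameters is not None else np.full(n, 5.0)
        prof = DiameterProfile(values=np.asarray(d, float),
                               positions=np.arange(len(d)))
        return VesselSegment(id=seg_id, frame_index=frame_index, path=path,
                             start=tuple(start), end=tuple(end),
                             length=n, profile=prof)

    return _make
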