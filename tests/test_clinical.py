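"""Diameter-curve smoothing, stenosis quantification/grading, bridges."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from angiotrack.clinical import (
    GRADE_NORMAL, detect_bridge, grade, quantify_stenosis, smooth_profile,
    stenosis_candidates,
)
from angiotrack.fusion import VesselTrack
from angiotrack.segments import DiameterProfile


def prof(values):
    values = np.asarray(values, float)
    return DiameterProfile(values=values, positions=np.arange(len(values)))


class TestSmoothProfile:
    def test_constant_unchanged(self):
        out = smooth_profile(prof([4, 4, 4, 4, 4]), 3)
        assert np.allclose(out.values, 4)

    def test_trailing_average_with_edge_shrink(self):
        out = smooth_profile(prof([1, 2, 3, 4]), 3)
        assert np.allclose(out.values, [1, 1.5, 2, 3])

    def test_window_one_is_identity(self):
        out = smooth_profile(prof([3, 1, 4, 1, 5]), 1)
        assert np.allclose(out.values, [3, 1, 4, 1, 5])

    def test_window_longer_than_profile_errors(self):
        with pytest.raises(ValueError):
            smooth_profile(prof([1, 2]), 3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(prof([1, 2, 3, 4]), 2)


class TestQuantifyStenosis:
    def test_closed_form_seventy_percent(self):
        findings = quantify_stenosis(prof([9, 10, 3, 10, 9]))
        assert len(findings) == 1
        f = findings[0]
        assert f.d_min == 3 and f.d_f == 10 and f.d_b == 10
        assert f.percent == pytest.approx(70.0)
        assert f.grade == 2

    def test_flat_profile_discarded_as_normal(self):
        assert quantify_stenosis(prof([5, 5, 5, 5, 5])) == []

    def test_monotone_profile_no_findings(self):
        assert quantify_stenosis(prof([9, 8, 7, 6, 5])) == []

    def test_peripheral_excludes_distal_fifth(self):
        # the only minimum sits in the distal 20 % of a leaf vessel
        values = [8.0] * 17 + [4.0, 8.0, 8.0]
        assert quantify_stenosis(prof(values), peripheral=True) == []
        # the same dip proximally is reported
        values = [8.0, 8.0, 4.0] + [8.0] * 17
        assert len(quantify_stenosis(prof(values), peripheral=True)) == 1

    def test_phantom_severity_within_ten_points(self):
        from angiotrack import phantom, pipeline
        spec = phantom.straight_vessel_spec(width=10, angle_deg=25, length=120)
        spec.stenoses = [phantom.LesionSpec(segment=0, position=0.5,
                                            severity=0.5, extent=24)]
        mask = phantom.render_vessel_mask(spec, 0)
        fr = pipeline.analyze_frame(mask)
        smoothed = fr.smoothed[fr.segments[0].id]
        findings = quantify_stenosis(smoothed)
        assert len(findings) == 1
        assert abs(findings[0].percent - 50.0) <= 10.0

    @given(d_min=st.floats(0.5, 6.0), d_f=st.floats(6.5, 15.0),
           d_b=st.floats(6.5, 15.0))
    def test_percent_matches_closed_form(self, d_min, d_f, d_b):
        values = [d_f - 0.2, d_f, d_min, d_b, d_b - 0.2]
        f = stenosis_candidates(prof(values))[0]
        expected = (1 - 2 * d_min / (d_f + d_b)) * 100
        assert f.percent == pytest.approx(expected, abs=1e-9)

    @given(st.floats(1.0, 9.9))
    def test_deeper_minimum_more_severe(self, d_min):
        base = stenosis_candidates(prof([10, 11, d_min, 11, 10]))[0].percent
        deeper = stenosis_candidates(prof([10, 11, d_min * 0.9, 11, 10]))[0].percent
        assert deeper > base


class TestGrade:
    @pytest.mark.parametrize("p,expected", [
        (79.3, 2),          # worked severe-stenosis classification
        (70.0, 2),
        (69.9, 1),
        (50.0, 1),
        (49.9, 0),
        (30.0, 0),
        (29.9, GRADE_NORMAL),
        (0.0, GRADE_NORMAL),
    ])
    def test_boundaries(self, p, expected):
        assert grade(p) == expected


def track(stenosis=None, diameter=None, n=None):
    st_map = dict(enumerate(stenosis or []))
    di_map = dict(enumerate(diameter or []))
    count = n or max(len(st_map), len(di_map))
    return VesselTrack(track_id=0, members=[(t, 0) for t in range(count)],
                       stenosis_degree=st_map, mean_diameter=di_map)


class TestDetectBridge:
    def test_rule_a_stenosis_variation(self):
        tr = track(stenosis=[0.20, 0.25, 0.30, 0.35, 0.50],
                   diameter=[10, 10, 10, 10, 10])
        f = detect_bridge(tr)
        assert f is not None and f.rule == "stenosis_variation"
        assert f.stenosis_max == 0.50 and f.stenosis_min == 0.20
        assert abs(f.stenosis_max_frame - f.stenosis_min_frame) >= 3

    def test_constant_stenosis_not_flagged(self):
        tr = track(stenosis=[0.5] * 5, diameter=[10] * 5)
        assert detect_bridge(tr) is None

    def test_rule_b_diameter_ratio(self):
        tr = track(stenosis=[0.0] * 5, diameter=[10, 10, 9, 8, 7])
        f = detect_bridge(tr)
        assert f is not None and f.rule == "diameter_ratio"
        assert f.average_min / f.average_max <= 0.75

    def test_transient_spike_without_spaced_pair_rejected(self):
        # large swing only between frames closer than the required gap
        tr = track(stenosis=[0.1, 0.5, 0.12, 0.3], diameter=[10] * 4)
        assert detect_bridge(tr) is None

    def test_repeated_extremes_still_satisfy_gap(self):
        # the max recurs next to the min; a far occurrence still counts
        tr = track(stenosis=[0.5, 0.1, 0.2, 0.5, 0.1],
                   diameter=[10] * 5)
        f = detect_bridge(tr)
        assert f is not None and f.rule == "stenosis_variation"
        assert abs(f.stenosis_max_frame - f.stenosis_min_frame) >= 3

    def test_short_track_skipped(self):
        tr = track(stenosis=[0.0, 0.5, 0.0], diameter=[10, 5, 10])
        assert detect_bridge(tr) is None

    def test_rule_a_checked_before_rule_b(self):
        tr = track(stenosis=[0.0, 0.1, 0.2, 0.5],
                   diameter=[10, 9, 8, 7])
        f = detect_bridge(tr)
        assert f.rule == "stenosis_variation"
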