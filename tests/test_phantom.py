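"""Phantom generator: rendering, truth sidecars, determinism, file I/O."""

import numpy as np
import pytest
from scipy import ndimage

from angiotrack import phantom
from angiotrack.io_cli import read_mask_sequence
from angiotrack.phantom import (
    CenterlineSpec, LesionSpec, PhantomSpec, PhantomTruth,
    PhantomValidationError, lesion_degree, make_sequence, render_vessel_mask,
    validate_truth, write_phantom,
)


class TestRender:
    def test_straight_vessel_area(self):
        spec = phantom.straight_vessel_spec(width=5, angle_deg=0, length=100)
        area = int(render_vessel_mask(spec, 0).sum())
        assert abs(area - 500) <= 50

    def test_deterministic(self):
        spec = phantom.random_tree_spec(seed=3, n_segments=4)
        a = render_vessel_mask(spec, 0)
        b = render_vessel_mask(spec, 0)
        assert np.array_equal(a, b)

    def test_severity_one_rejected(self):
        spec = phantom.straight_vessel_spec()
        spec.stenoses = [LesionSpec(segment=0, position=0.5, severity=1.0,
                                    extent=10)]
        with pytest.raises(PhantomValidationError, match="severity"):
            render_vessel_mask(spec, 0)

    def test_thin_width_rejected(self):
        spec = PhantomSpec(segments=[CenterlineSpec(points=[(5, 5), (50, 50)],
                                                    base_width=2.0)])
        with pytest.raises(PhantomValidationError, match="base_width"):
            render_vessel_mask(spec, 0)

    def test_detached_child_rejected(self):
        spec = PhantomSpec(segments=[
            CenterlineSpec(points=[(5, 5), (50, 50)], base_width=5),
            CenterlineSpec(points=[(80, 80), (120, 120)], base_width=4, parent=0),
        ])
        with pytest.raises(PhantomValidationError, match="parent"):
            render_vessel_mask(spec, 0)

    def test_frame_out_of_range(self):
        spec = phantom.straight_vessel_spec()
        with pytest.raises(PhantomValidationError):
            render_vessel_mask(spec, 1)

    def test_border_clipping_marked_in_truth(self):
        spec = PhantomSpec(image_height=64, image_width=64,
                           segments=[CenterlineSpec(points=[(40, 40), (90, 40)],
                                                    base_width=5)])
        masks, truth = make_sequence(spec)
        assert truth.frames[0]["segments"][0]["clipped"]
        assert masks[0][:, -1].sum() > 0  # reaches the border, no crash

    def test_width_fidelity_against_distance_transform(self):
        # 2x the Euclidean distance transform at the true centerline must
        # equal the base width within +-1 px at >= 95 % of interior samples
        spec = phantom.straight_vessel_spec(width=7, angle_deg=20, length=100)
        mask = render_vessel_mask(spec, 0)
        _, truth = make_sequence(spec)
        edt = ndimage.distance_transform_edt(mask)
        cl = np.asarray(truth.frames[0]["segments"][0]["centerline"])[10:-10]
        vals = 2 * edt[np.round(cl[:, 1]).astype(int), np.round(cl[:, 0]).astype(int)]
        assert np.mean(np.abs(vals - 7) <= 1.0) >= 0.95


class TestMakeSequence:
    def test_motion_translates_truth(self):
        spec = phantom.random_tree_spec(seed=1, n_segments=3, n_frames=5,
                                        motion_per_frame=(3, 3))
        masks, truth = make_sequence(spec)
        assert len(masks) == 5 and truth.n_frames == 5
        c0 = np.asarray(truth.frames[0]["segments"][0]["centerline"])
        c4 = np.asarray(truth.frames[4]["segments"][0]["centerline"])
        assert np.allclose(c4 - c0, 12.0)
        # correspondence ids persist across every frame
        for fr in truth.frames:
            assert [s["correspondence_id"] for s in fr["segments"]] == [0, 1, 2]

    def test_periodic_degree_closed_form(self):
        les = LesionSpec(segment=0, position=0.5, severity=0.5, extent=10,
                         periodic=True, period_frames=6)
        degrees = [lesion_degree(les, t) for t in range(12)]
        assert max(degrees) == pytest.approx(0.5)
        assert min(degrees) == pytest.approx(0.0)
        assert degrees[0] == pytest.approx(0.5) and degrees[3] == pytest.approx(0.0)

    def test_same_spec_bit_identical(self):
        spec = phantom.lesion_sequence_spec(seed=9, periodic=True, n_frames=4)
        m1, t1 = make_sequence(spec)
        m2, t2 = make_sequence(spec)
        assert all(np.array_equal(a, b) for a, b in zip(m1, m2))
        assert t1.to_dict() == t2.to_dict()

    def test_bifurcation_count_matches_parent_arity(self):
        spec = phantom.random_tree_spec(seed=4, n_segments=6)
        _, truth = make_sequence(spec)
        parents = {}
        for s in spec.segments:
            if s.parent is not None:
                parents[s.parent] = parents.get(s.parent, 0) + 1
        expected = sum(1 for k in parents.values() if k >= 2)
        assert len(truth.frames[0]["bifurcations"]) == expected


class TestWritePhantom:
    def test_round_trip_bit_identical(self, tmp_path):
        spec = phantom.random_tree_spec(seed=2, n_segments=3, n_frames=3,
                                        motion_per_frame=(2, 1))
        masks, truth = make_sequence(spec)
        write_phantom(str(tmp_path), masks, truth)
        back = read_mask_sequence(str(tmp_path))
        assert len(back) == 3
        assert all(np.array_equal(a, b) for a, b in zip(masks, back))

    def test_zero_frames_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_phantom(str(tmp_path), [], None)

    def test_truth_json_validates(self, tmp_path):
        import json
        spec = phantom.random_tree_spec(seed=2, n_segments=3)
        masks, truth = make_sequence(spec)
        write_phantom(str(tmp_path), masks, truth)
        with open(tmp_path / "truth.json") as fh:
            loaded = json.load(fh)
        validate_truth(loaded)
        assert PhantomTruth.from_dict(loaded).n_frames == 1

    def test_invalid_truth_rejected(self):
        with pytest.raises(PhantomValidationError, match="frame record"):
            validate_truth({"image_height": 1, "image_width": 1,
                            "n_frames": 2, "frames": [], "lesions": []})
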