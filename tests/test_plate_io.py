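import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonytrack.plate_io import (
    PlateROI,
    ScanFrame,
    assemble_video,
    detect_plate_circle,
    local_roi,
    parse_time_axis,
    plan_layout,
    rois_from_layout,
    split_plates,
)


class TestParseTimeAxis:
    def test_interval_cadence(self):
        names = [f"scan_{i}.png" for i in range(4)]
        axis = parse_time_axis(names, "interval", interval_min=15)
        assert [t for _, t in axis] == [0.0, 0.25, 0.5, 0.75]

    def test_single_frame(self):
        assert parse_time_axis(["a.png"], "interval", interval_min=5) == [("a.png", 0.0)]

    def test_pattern_timestamps(self):
        names = ["plate_08:30.png", "plate_08:00.png", "plate_09:00.png"]
        axis = parse_time_axis(names, "pattern", pattern=r"plate_(\d\d:\d\d)")
        assert [n for n, _ in axis] == ["plate_08:00.png", "plate_08:30.png", "plate_09:00.png"]
        assert [t for _, t in axis] == pytest.approx([0.0, 0.5, 1.0])

    def test_duplicate_timestamp_names_files(self):
        with pytest.raises(ValueError, match="a_08:00.*b_08:00|duplicate"):
            parse_time_axis(
                ["a_08:00.png", "b_08:00.png"], "pattern", pattern=r"_(\d\d:\d\d)"
            )

    def test_unmatched_filename_named(self):
        with pytest.raises(ValueError, match="oops"):
            parse_time_axis(["a_08:00.png", "oops.png"], "pattern", pattern=r"_(\d\d:\d\d)")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            parse_time_axis([], "interval", interval_min=15)

    @given(n=st.integers(1, 40), interval=st.floats(0.5, 120))
    @settings(max_examples=50, deadline=None)
    def test_monotone_from_zero(self, n, interval):
        axis = parse_time_axis([f"f{i:03d}" for i in range(n)], "interval", interval_min=interval)
        times = [t for _, t in axis]
        assert times[0] == 0.0
        assert all(b > a for a, b in zip(times, times[1:]))


class TestPlanLayout:
    def test_six_three_inch_plates_on_a4_bed(self):
        assert len(plan_layout(216, 297, 76.2)) == 6

    def test_plate_exceeding_bed(self):
        assert plan_layout(50, 50, 76.2) == []

    def test_two_by_two_against_enumeration(self):
        # brute-force oracle: largest c x r axis-aligned grid of d-circles
        def brute(w, h, d):
            best = 0
            for c in range(1, 20):
                for r in range(1, 20):
                    if c * d <= w and r * d <= h:
                        best = max(best, c * r)
            return best

        centers = plan_layout(100, 100, 50)
        assert len(centers) == brute(100, 100, 50) == 4

    @given(
        w=st.floats(10, 500),
        h=st.floats(10, 500),
        d=st.floats(5, 200),
        m=st.floats(0, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_circles_disjoint_and_inside(self, w, h, d, m):
        centers = plan_layout(w, h, d, m)
        r = d / 2.0
        for cx, cy in centers:
            assert r - 1e-9 <= cx <= w - r + 1e-9
            assert r - 1e-9 <= cy <= h - r + 1e-9
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                dx = centers[i][0] - centers[j][0]
                dy = centers[i][1] - centers[j][1]
                assert np.hypot(dx, dy) >= d - 1e-9


class TestSplitPlates:
    def _frame(self, shape=(300, 300), fill=0.5):
        return ScanFrame(0, 0.0, np.full(shape, fill))

    def test_bounding_square_size(self):
        roi = PlateROI("p", 150.0, 150.0, 50.0, 0.254)
        (crop,) = split_plates(self._frame(), [roi])
        assert crop.image.shape == (100, 100)

    def test_outside_circle_masked(self):
        roi = PlateROI("p", 150.0, 150.0, 50.0, 0.254)
        (crop,) = split_plates(self._frame(), [roi])
        assert np.isnan(crop.image[0, 0])
        assert crop.image[50, 50] == 0.5

    def test_roi_beyond_frame_names_plate(self):
        roi = PlateROI("edge_plate", 49.0, 150.0, 50.0, 0.254)
        with pytest.raises(ValueError, match="edge_plate"):
            split_plates(self._frame(), [roi])

    def test_six_plate_bed_yields_six_crops(self):
        centers = plan_layout(216, 297, 76.2)
        rois = rois_from_layout(centers, 76.2, 25.4)  # 1 px per mm
        frame = ScanFrame(0, 0.0, np.random.default_rng(0).uniform(size=(297, 216)))
        crops = split_plates(frame, rois)
        assert len(crops) == 6

    def test_crops_match_source_inside_mask(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(size=(297, 216))
        frame = ScanFrame(0, 0.0, img)
        rois = rois_from_layout(plan_layout(216, 297, 76.2), 76.2, 25.4)
        for roi, crop in zip(rois, split_plates(frame, rois)):
            loc = local_roi(roi)
            x0 = int(roi.center_x_px - loc.center_x_px)
            y0 = int(roi.center_y_px - loc.center_y_px)
            side = crop.image.shape[0]
            ref = img[y0 : y0 + side, x0 : x0 + side]
            inside = ~np.isnan(crop.image)
            assert np.array_equal(crop.image[inside], ref[inside])


class TestDetectPlateCircle:
    def _disk(self, shape, cx, cy, r, hi=0.8, lo=0.1):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.full(shape, lo)
        img[np.hypot(xx - cx, yy - cy) <= r] = hi
        return img

    def test_recovers_disk_center_and_radius(self):
        img = self._disk((256, 256), 130.0, 120.0, 100.0)
        roi = detect_plate_circle(img, expected_radius_px=100, tolerance_frac=0.1)
        assert roi is not None
        assert abs(roi.center_x_px - 130) <= 2 and abs(roi.center_y_px - 120) <= 2
        assert abs(roi.radius_px - 100) / 100 <= 0.02

    def test_uniform_image_not_found(self):
        assert detect_plate_circle(np.full((128, 128), 0.3), 40) is None

    def test_hint_selects_nearby_disk(self):
        img = np.full((256, 420), 0.1)
        for cx in (100.0, 320.0):
            yy, xx = np.mgrid[0:256, 0:420]
            img[np.hypot(xx - cx, yy - 128.0) <= 80] = 0.8
        roi = detect_plate_circle(img, 80, hint_center=(320.0, 128.0), hint_window_px=60)
        assert roi is not None
        assert abs(roi.center_x_px - 320) <= 3


class TestAssembleVideo:
    def test_frame_count_preserved(self, tmp_path):
        frames = [ScanFrame(i, float(i), np.full((32, 32), i / 10)) for i in range(10)]
        out = assemble_video(frames, tmp_path / "movie.gif", fps=5)
        import imageio.v2 as iio

        rd = iio.mimread(out)
        assert len(rd) == 10

    def test_moving_dot_order(self, tmp_path):
        frames = []
        for k in range(6):
            img = np.zeros((24, 24))
            img[12, 3 * k + 2] = 1.0
            frames.append(ScanFrame(k, float(k), img))
        out = assemble_video(frames, tmp_path / "dot.gif", fps=2)
        import imageio.v2 as iio

        for k, fr in enumerate(iio.mimread(out)):
            fr2 = fr[..., 0] if fr.ndim == 3 else fr
            assert np.unravel_index(np.argmax(fr2), fr2.shape) == (12, 3 * k + 2)

    def test_empty_and_mixed_dims_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            assemble_video([], tmp_path / "x.gif")
        frames = [
            ScanFrame(0, 0.0, np.zeros((10, 10))),
            ScanFrame(1, 1.0, np.zeros((12, 12))),
        ]
        with pytest.raises(ValueError):
            assemble_video(frames, tmp_path / "x.gif")
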