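"""Rendering, LoG detection, subpixel refinement and linking."""

import numpy as np
import pytest

import locusdyn as ld
from locusdyn.detect import SpotDetection, detect_spots, link_tracks, refine_subpixel


def _render_spot(x_um, y_um, photons=5000, shape=(32, 32), seed=0):
    track = ld.Track(0, np.arange(2), [x_um, x_um], [y_um, y_um], dt=0.1)
    track.x_true, track.y_true = track.x.copy(), track.y.copy()
    imaging = ld.ImagingParams(
        pixel_size=0.16, frame_shape=shape, psf_sigma=0.15,
        photons_per_spot=photons, background=10, gaussian_read_noise=1,
    )
    return ld.render_movie([track], imaging, seed=seed).frames[0]


class TestRenderMovie:
    def test_background_only_mean(self):
        track = ld.Track(0, np.arange(3), np.full(3, 2.0), np.full(3, 2.0), dt=0.1)
        imaging = ld.ImagingParams(
            pixel_size=0.16, frame_shape=(64, 64), psf_sigma=0.15,
            photons_per_spot=0, background=10, gaussian_read_noise=1,
        )
        stack = ld.render_movie([track], imaging, seed=1)
        assert abs(stack.frames.mean() - 10) < 0.5

    def test_photon_conservation(self):
        """Background-subtracted intensity in a wide window ≈ photon count."""
        photons = 5000
        frame = _render_spot(2.56, 2.56, photons=photons).astype(float)
        win = frame[4:28, 4:28]
        total = win.sum() - 10 * win.size
        assert abs(total - photons) < 4 * np.sqrt(photons + 10 * win.size)

    def test_bit_identical_reruns(self):
        a = _render_spot(2.0, 3.0, seed=7)
        b = _render_spot(2.0, 3.0, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_out_of_fov_rejected(self):
        track = ld.Track(3, np.arange(2), [100.0, 100.0], [2.0, 2.0], dt=0.1)
        imaging = ld.ImagingParams(pixel_size=0.16, frame_shape=(32, 32), psf_sigma=0.15)
        with pytest.raises(ValueError, match="track 3"):
            ld.render_movie([track], imaging, seed=1)

    def test_roundtrip_io(self, tmp_path):
        track = ld.Track(0, np.arange(2), [2.0, 2.1], [2.0, 2.0], dt=0.1)
        imaging = ld.ImagingParams(pixel_size=0.16, frame_shape=(32, 32), psf_sigma=0.15)
        stack = ld.render_movie([track], imaging, seed=2)
        ld.write_movie(stack, tmp_path / "m.tif")
        back = ld.read_movie(tmp_path / "m.tif")
        np.testing.assert_array_equal(back.frames, stack.frames)
        assert back.dt == stack.dt and back.pixel_size == stack.pixel_size
        assert len(back.truth) == len(stack.truth)


class TestDetectSpots:
    def test_uniform_noise_gives_nothing_above_threshold(self):
        rng = np.random.default_rng(3)
        frame = rng.poisson(10, size=(64, 64)).astype(float)
        spots = detect_spots(frame, 0.16, expected_radius=0.3, quality_threshold=30.0)
        assert spots == []

    def test_single_spot_within_one_pixel(self):
        frame = _render_spot(2.56, 3.20)
        spots = detect_spots(frame, 0.16, expected_radius=0.3, quality_threshold=30.0)
        assert len(spots) == 1
        assert abs(spots[0].x - 2.56) < 0.16 and abs(spots[0].y - 3.20) < 0.16

    def test_two_separated_spots(self):
        t1 = ld.Track(0, np.arange(1), [1.6], [1.6], dt=0.1)
        t2 = ld.Track(1, np.arange(1), [3.52], [3.52], dt=0.1)
        imaging = ld.ImagingParams(
            pixel_size=0.16, frame_shape=(32, 32), psf_sigma=0.15,
            photons_per_spot=5000, background=10, gaussian_read_noise=1,
        )
        frame = ld.render_movie([t1, t2], imaging, seed=4).frames[0]
        spots = detect_spots(frame, 0.16, expected_radius=0.3, quality_threshold=30.0)
        assert len(spots) == 2

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        frame = rng.poisson(50, size=(128, 128)).astype(float)
        counts = [
            len(detect_spots(frame, 0.16, 0.3, thr)) for thr in (1.0, 3.0, 10.0, 30.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_non_finite_rejected(self):
        frame = np.ones((16, 16))
        frame[3, 3] = np.nan
        with pytest.raises(ValueError):
            detect_spots(frame, 0.16, 0.3, 1.0)


class TestRefineSubpixel:
    def test_pixel_centre_spot_stays_centred(self):
        # (15.5 + eps) px * 0.16 -> exactly a pixel centre
        frame = _render_spot(15.5 * 0.16, 15.5 * 0.16, photons=50000)
        spots = detect_spots(frame, 0.16, 0.3, 30.0)
        refined = refine_subpixel(frame, spots, 0.16)
        assert abs(refined[0].x / 0.16 - 15.5) < 0.05
        assert abs(refined[0].y / 0.16 - 15.5) < 0.05

    def test_known_subpixel_offset(self):
        x, y = (15 + 0.3) * 0.16, (15 + 0.7) * 0.16
        frame = _render_spot(x, y, photons=50000)
        spots = detect_spots(frame, 0.16, 0.3, 30.0)
        refined = refine_subpixel(frame, spots, 0.16)
        assert abs(refined[0].x - x) / 0.16 < 0.1
        assert abs(refined[0].y - y) / 0.16 < 0.1

    def test_localization_rmse_under_015_px(self):
        """200 random subpixel placements: per-coordinate RMSE < 0.15 px."""
        rng = np.random.default_rng(6)
        errs = []
        for i in range(200):
            cx = (12 + rng.random()) * 0.16
            cy = (12 + rng.random()) * 0.16
            frame = _render_spot(cx, cy, photons=5000, shape=(26, 26), seed=100 + i)
            spots = detect_spots(frame, 0.16, 0.3, 30.0)
            if not spots:
                continue
            r = refine_subpixel(frame, spots[:1], 0.16)[0]
            errs.append(((r.x - cx) / 0.16, (r.y - cy) / 0.16))
        errs = np.array(errs)
        assert len(errs) > 180
        assert np.sqrt(np.mean(errs**2)) < 0.15

    def test_border_spot_kept_with_warning(self):
        frame = np.ones((16, 16))
        spot = SpotDetection(frame=0, x=0.08, y=0.08, intensity=1.0, quality=1.0)
        with pytest.warns(UserWarning):
            out = refine_subpixel(frame, [spot], 0.16)
        assert out[0].x == spot.x and out[0].y == spot.y

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError):
            refine_subpixel(np.ones((16, 16)), [], 0.16, window=4)


class TestLinkTracks:
    @staticmethod
    def _dets(positions):
        """positions: list per frame of (x, y) tuples."""
        return [
            [SpotDetection(frame=f, x=x, y=y, intensity=1.0, quality=1.0) for x, y in pts]
            for f, pts in enumerate(positions)
        ]

    def test_single_detection_chain(self):
        dets = self._dets([[(1.0 + 0.01 * f, 2.0)] for f in range(100)])
        tracks = link_tracks(dets, max_disp=0.5, max_gap=2, dt=0.1)
        assert len(tracks) == 1
        assert len(tracks[0]) == 100

    def test_two_distant_loci_never_swap(self):
        rng = np.random.default_rng(7)
        pos_a = np.cumsum(rng.normal(0, 0.02, size=(200, 2)), axis=0) + [2.0, 2.0]
        pos_b = np.cumsum(rng.normal(0, 0.02, size=(200, 2)), axis=0) + [12.0, 12.0]
        dets = self._dets(
            [[(a[0], a[1]), (b[0], b[1])] for a, b in zip(pos_a, pos_b)]
        )
        tracks = link_tracks(dets, max_disp=0.5, max_gap=2, dt=0.1)
        assert len(tracks) == 2
        for tr in tracks:
            start_near_a = np.hypot(tr.x[0] - pos_a[0, 0], tr.y[0] - pos_a[0, 1]) < 1
            ref = pos_a if start_near_a else pos_b
            assert np.max(np.hypot(tr.x - ref[:, 0], tr.y - ref[:, 1])) < 1.0

    def test_gap_longer_than_max_gap_splits_track(self):
        pts = [[(1.0, 1.0)]] * 10 + [[]] * 3 + [[(1.0, 1.0)]] * 10
        dets = self._dets(pts)
        tracks = link_tracks(dets, max_disp=0.5, max_gap=2, dt=0.1)
        assert len(tracks) == 2

    def test_gap_within_max_gap_bridged(self):
        pts = [[(1.0, 1.0)]] * 10 + [[]] * 2 + [[(1.0, 1.0)]] * 10
        tracks = link_tracks(self._dets(pts), max_disp=0.5, max_gap=2, dt=0.1)
        assert len(tracks) == 1
        assert np.all(np.diff(tracks[0].frames) >= 1)

    def test_no_duplicate_frames_within_track(self):
        rng = np.random.default_rng(8)
        pts = [
            [(float(rng.uniform(0, 5)), float(rng.uniform(0, 5))) for _ in range(4)]
            for _ in range(50)
        ]
        tracks = link_tracks(self._dets(pts), max_disp=1.0, max_gap=2, dt=0.1)
        for tr in tracks:
            assert len(np.unique(tr.frames)) == len(tr.frames)


class TestFilterTracks:
    def _track(self, n, dt=0.1):
        return ld.Track(0, np.arange(n), np.zeros(n), np.zeros(n), dt=dt)

    def test_boundary_inclusive(self):
        assert ld.filter_tracks([self._track(201)], min_duration=20.0)

    def test_short_track_removed(self):
        assert ld.filter_tracks([self._track(150)], min_duration=20.0) == []

    def test_empty_and_idempotent(self):
        assert ld.filter_tracks([], 20.0) == []
        tracks = [self._track(250), self._track(100)]
        once = ld.filter_tracks(tracks, 20.0)
        assert ld.filter_tracks(once, 20.0) == once
        assert set(id(t) for t in once) <= set(id(t) for t in tracks)
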