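import numpy as np
import pytest

from foldshape import comet_tracking as ct
from foldshape.config import PipelineConfig
from foldshape.synthetic_data import CometMovieParams, generate_comet_movie
from foldshape.types import CometSpot, CometTrack, RoiRect, TimeLapse2D


def brute_force_otsu(frame):
    """Exhaustive between-class-variance maximization over all 255 cuts."""
    vals = frame.ravel()
    best_t, best_var = None, -1.0
    for t in range(255):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo), len(hi)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    return best_t


class TestPrepareMovie:
    def _movie(self, n_frames=150, value=None):
        rng = np.random.default_rng(0)
        frames = rng.random((n_frames, 60, 70)) * 100 \
            if value is None else np.full((n_frames, 60, 70), value)
        return TimeLapse2D(frames, (0.2, 0.2), 4.0)

    def test_duration_crop_frame_count(self):
        out = ct.prepare_movie(self._movie(), duration=200.0)
        assert out.n_frames == 50  # 200 s at 4 s/frame

    def test_min_max_rescale_endpoints(self):
        frames = np.tile(np.linspace(10, 210, 100).reshape(1, 10, 10),
                         (5, 1, 1))
        movie = TimeLapse2D(frames, (0.2, 0.2), 4.0)
        out = ct.prepare_movie(movie, duration=20.0)
        assert out.frames.min() == 0 and out.frames.max() == 255
        assert out.frames.dtype == np.uint8

    def test_constant_movie_maps_to_zero(self):
        out = ct.prepare_movie(self._movie(value=37.0), duration=20.0)
        assert (out.frames == 0).all()

    def test_spatial_crop(self):
        roi = RoiRect((1.0, 2.0), 10.0, 8.0)
        out = ct.prepare_movie(self._movie(), duration=20.0, roi=roi)
        assert out.frames.shape[1:] == (40, 50)  # 8/0.2 × 10/0.2

    def test_short_movie_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ct.prepare_movie(self._movie(n_frames=10), duration=200.0)


class TestOtsu:
    def test_two_level_image(self):
        rng = np.random.default_rng(1)
        frame = np.full((50, 50), 20, dtype=np.uint8)
        frame[10:14, 10:14] = 200
        frame[30:33, 35:39] = 200
        t = ct.otsu_threshold(frame)
        assert 20 <= t < 200
        parts = ct.segment_particles(frame, 0.01, 50.0, (0.5, 0.5),
                                     presmooth_um=0.0)
        assert len(parts) == 2

    def test_matches_brute_force_on_noise(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            frame = rng.integers(0, 256, (40, 40)).astype(np.uint8)
            assert ct.otsu_threshold(frame) == brute_force_otsu(frame)

    def test_single_valued_histogram_none(self):
        assert ct.otsu_threshold(np.zeros((10, 10), dtype=np.uint8)) is None


class TestSegmentParticles:
    def test_empty_frame_no_particles(self):
        parts = ct.segment_particles(np.zeros((20, 20), dtype=np.uint8),
                                     0.01, 5.0, (0.2, 0.2))
        assert parts == []

    def test_area_filter(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[5:7, 5:7] = 200        # 4 px = 1 μm² at 0.5 μm/px
        frame[20:30, 20:30] = 200    # 100 px = 25 μm²
        parts = ct.segment_particles(frame, 0.5, 5.0, (0.5, 0.5),
                                     presmooth_um=0.0)
        assert len(parts) == 1
        (cx, cy), area = parts[0]
        assert area == pytest.approx(1.0)
        assert (cx, cy) == pytest.approx((3.0, 3.0))


class TestDetectLog:
    SPACING = (0.2, 0.2)

    def _blob_frame(self, centers_um, sigma_um=0.354, shape=(80, 80)):
        frame = np.zeros(shape, dtype=np.float64)
        ys = (np.arange(shape[0]) + 0.5) * self.SPACING[1]
        xs = (np.arange(shape[1]) + 0.5) * self.SPACING[0]
        for cx, cy in centers_um:
            frame += 200 * np.exp(-((xs[None, :] - cx) ** 2
                                    + (ys[:, None] - cy) ** 2)
                                  / (2 * sigma_um ** 2))
        return frame.astype(np.uint8)

    def test_single_blob_subpixel_accuracy(self):
        truth = (7.93, 8.11)
        frame = self._blob_frame([truth])
        spots = ct.detect_log(frame, self.SPACING, auto_quality=False,
                              quality_threshold=5.0)
        assert len(spots) == 1
        x, y = spots[0].position
        # within 0.2 px of the injected center
        assert abs(x - truth[0]) < 0.2 * self.SPACING[0]
        assert abs(y - truth[1]) < 0.2 * self.SPACING[1]

    def test_blank_frame_no_spots(self):
        spots = ct.detect_log(np.zeros((40, 40), dtype=np.uint8),
                              self.SPACING)
        assert spots == []

    def test_two_distant_blobs(self):
        frame = self._blob_frame([(4.0, 4.0), (9.0, 4.0)])  # 5 μm apart
        spots = ct.detect_log(frame, self.SPACING, auto_quality=False,
                              quality_threshold=5.0)
        assert len(spots) == 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        frame = np.clip(self._blob_frame([(4, 4), (10, 7), (12, 3)])
                        + rng.normal(0, 10, (80, 80)), 0,
                        255).astype(np.uint8)
        counts = [len(ct.detect_log(frame, self.SPACING, auto_quality=False,
                                    quality_threshold=q))
                  for q in (0.5, 2.0, 5.0, 20.0, 60.0)]
        assert counts == sorted(counts, reverse=True)

    def test_undetectable_scale_rejected(self):
        with pytest.raises(ValueError, match="blob_diameter"):
            ct.detect_log(np.zeros((10, 10), dtype=np.uint8), (1.0, 1.0),
                          blob_diameter=1.0)


def _spots(path, start_frame=0):
    """path: list of (x, y) per frame → {frame: [CometSpot]} merging dicts."""
    out = {}
    for f, pos in enumerate(path, start=start_frame):
        out.setdefault(f, [])
        if pos is not None:
            out[f].append(CometSpot(frame=f, position=pos))
    return out


def merge(*dicts):
    out = {}
    for d in dicts:
        for f, spots in d.items():
            out.setdefault(f, []).extend(spots)
    return out


class TestLinking:
    def test_single_constant_velocity_track(self):
        path = [(1.0 + 0.3 * f, 2.0) for f in range(10)]
        tracks = ct.link_tracks(_spots(path), frame_interval=4.0)
        assert len(tracks) == 1
        assert len(tracks[0].spots) == 10
        assert tracks[0].mean_speed == pytest.approx(0.3 / 4 * 60)

    def test_crossing_comets_keep_identity_by_prediction(self):
        # two comets pass within the link radius with opposite velocities
        a = [(0.5 + 0.3 * f, 5.0) for f in range(12)]
        b = [(4.1 - 0.3 * f, 5.4) for f in range(12)]
        tracks = ct.link_tracks(merge(_spots(a), _spots(b)),
                                max_link_radius=1.5)
        assert len(tracks) == 2
        xs_end = sorted(t.spots[-1].position[0] for t in tracks)
        xs_start = sorted(t.spots[0].position[0] for t in tracks)
        # the rightward starter ends rightmost; no identity swap
        for t in tracks:
            dxs = np.diff([s.position[0] for s in t.spots])
            assert (dxs > 0).all() or (dxs < 0).all()

    def test_gap_closing_bridges_one_missed_detection(self):
        path = [(1.0 + 0.3 * f, 2.0) if f != 5 else None for f in range(12)]
        tracks = ct.link_tracks(_spots(path), gap_frames=1)
        assert len(tracks) == 1
        frames = [s.frame for s in tracks[0].spots]
        assert frames == [f for f in range(12) if f != 5]

    def test_no_gap_closing_splits_track(self):
        path = [(1.0 + 0.3 * f, 2.0) if f != 5 else None for f in range(12)]
        tracks = ct.link_tracks(_spots(path), gap_frames=0)
        assert len(tracks) == 2

    def test_min_track_length_filter(self):
        path = [(1.0 + 0.3 * f, 2.0) for f in range(2)]
        assert ct.link_tracks(_spots(path), min_track_length=3) == []

    def test_empty_input(self):
        assert ct.link_tracks({}) == []


class TestTrackSpeed:
    def test_per_frame_displacement_to_um_per_min(self):
        spots = [CometSpot(frame=f, position=(0.3 * f, 0.0))
                 for f in range(5)]
        track = CometTrack(spots=spots)
        assert ct.track_speed(track, 4.0) == pytest.approx(4.5)

    def test_stationary_zero(self):
        spots = [CometSpot(frame=f, position=(1.0, 1.0)) for f in range(5)]
        assert ct.track_speed(CometTrack(spots=spots), 4.0) == 0.0

    def test_single_spot_rejected(self):
        with pytest.raises(ValueError):
            ct.track_speed(CometTrack(spots=[CometSpot(0, (0.0, 0.0))]), 4.0)


class TestSummarize:
    def test_empty_movie_zero_comets(self):
        movie = TimeLapse2D(np.zeros((10, 50, 50), dtype=np.uint8),
                            (0.2, 0.2), 4.0)
        s = ct.summarize_comets(movie)
        assert s.comet_number == 0.0
        assert s.n_tracks == 0
        assert s.mean_speed is None

    def test_speed_recovered_from_generated_movie(self, comet_movie_default):
        from foldshape.synthetic_data import observable_track_speeds
        params, movie, truth = comet_movie_default
        roi = RoiRect((5.0, 5.0), 50.0, 40.0)
        prep = ct.prepare_movie(movie, duration=200.0, roi=roi)
        s = ct.summarize_comets(prep, PipelineConfig())
        true_mean = observable_track_speeds(truth, roi, prep.n_frames).mean()
        assert s.mean_speed == pytest.approx(true_mean, rel=0.05)

    def test_count_recovered_from_generated_movie(self, comet_movie_default):
        params, movie, truth = comet_movie_default
        prep = ct.prepare_movie(movie, duration=200.0,
                                roi=RoiRect((5.0, 5.0), 50.0, 40.0))
        s = ct.summarize_comets(prep, PipelineConfig())
        pos = truth["positions"]
        pos = pos[pos["frame"] < prep.n_frames]
        in_roi = pos[(pos.x_um >= 5) & (pos.x_um < 55)
                     & (pos.y_um >= 5) & (pos.y_um < 45)]
        true_count = in_roi.groupby("frame").size().mean()
        assert s.comet_number == pytest.approx(true_count, rel=0.10)

    def test_determinism(self, comet_movie_default):
        _, movie, _ = comet_movie_default
        prep = ct.prepare_movie(movie, duration=100.0)
        s1 = ct.summarize_comets(prep, PipelineConfig())
        s2 = ct.summarize_comets(prep, PipelineConfig())
        assert s1 == s2
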