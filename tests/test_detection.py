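import numpy as np
import pytest

from livespot.detection import (DetectionParams, auto_threshold, detect_spots,
                                flag_clusters, log_filter)
from livespot.simulator import render_noiseless_frame


class TestLogFilter:
    def test_flat_field_response_is_zero(self):
        resp = log_filter(np.full((32, 32), 500.0), sigma_px=1.5)
        # the truncated discrete kernel leaves a ~4e-4 relative residual
        assert np.abs(resp).max() < 1e-3 * 500

    def test_peak_at_spot_center_for_matched_sigma(self):
        frame = render_noiseless_frame(np.array([[16.0, 20.0]]), np.array([100.0]),
                                       (40, 40), 1.5)
        resp = log_filter(frame, 1.5)
        assert np.unravel_index(np.argmax(resp), resp.shape) == (16, 20)

    def test_linearity(self, rng):
        img = rng.uniform(0, 100, size=(24, 24))
        np.testing.assert_allclose(log_filter(3.0 * img, 1.2),
                                   3.0 * log_filter(img, 1.2), rtol=1e-9)


class TestDetectSpots:
    def test_blank_noisy_image_with_high_threshold(self, rng):
        img = rng.normal(100, 5, size=(64, 64))
        params = DetectionParams(sigma_px=1.3, threshold=50.0)
        assert len(detect_spots(img, params)) == 0

    def test_subpixel_centroid_accuracy(self):
        y0, x0, sigma = 50.3, 20.7, 1.3
        frame = render_noiseless_frame(np.array([[y0, x0]]), np.array([200.0]),
                                       (80, 80), sigma)
        params = DetectionParams(sigma_px=sigma, threshold=10.0)
        spots = detect_spots(frame, params)
        assert len(spots) == 1
        assert abs(spots.loc[0, "y_px"] - y0) < 0.1
        assert abs(spots.loc[0, "x_px"] - x0) < 0.1

    def test_translation_equivariance(self, rng):
        pos = np.array([[20.0, 22.0], [40.0, 50.0], [55.0, 15.0]])
        frame = render_noiseless_frame(pos, np.full(3, 150.0), (80, 80), 1.3)
        params = DetectionParams(sigma_px=1.3, threshold=20.0)
        base = detect_spots(frame, params).sort_values("y_px")
        dy, dx = 5, 7
        shifted_frame = render_noiseless_frame(pos + [dy, dx], np.full(3, 150.0),
                                               (80, 80), 1.3)
        shifted = detect_spots(shifted_frame, params).sort_values("y_px")
        np.testing.assert_allclose(shifted["y_px"].to_numpy(),
                                   base["y_px"].to_numpy() + dy, atol=1e-6)
        np.testing.assert_allclose(shifted["x_px"].to_numpy(),
                                   base["x_px"].to_numpy() + dx, atol=1e-6)

    def test_raising_threshold_never_increases_count(self, rng):
        pos = rng.uniform(10, 110, size=(15, 2))
        frame = render_noiseless_frame(pos, rng.uniform(50, 200, 15), (128, 128), 1.3)
        frame = frame + rng.normal(100, 5, frame.shape)
        counts = []
        for th in np.geomspace(3, 120, 12):
            counts.append(len(detect_spots(frame, DetectionParams(sigma_px=1.3,
                                                                  threshold=th))))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_unresolved_threshold_rejected(self):
        with pytest.raises(ValueError, match="AUTO"):
            detect_spots(np.zeros((16, 16)), DetectionParams(threshold=None))


class TestAutoThreshold:
    def test_noiseless_equal_spots_recovered_exactly(self):
        pos = np.array([[15.0, 15.0], [15.0, 45.0], [45.0, 15.0], [45.0, 45.0],
                        [30.0, 30.0]])
        frame = render_noiseless_frame(pos, np.full(5, 100.0), (64, 64), 1.3)
        auto = auto_threshold([frame], sigma_px=1.3)
        spots = detect_spots(frame, DetectionParams(sigma_px=1.3,
                                                    threshold=auto.threshold))
        assert len(spots) == 5

    def test_threshold_inside_brute_force_plateau(self, rng):
        pos = rng.uniform(12, 116, size=(20, 2))
        frame = render_noiseless_frame(pos, np.full(20, 100.0), (128, 128), 1.3)
        frame = frame + rng.normal(200, 5, frame.shape)
        auto = auto_threshold([frame], sigma_px=1.3)
        # brute-force scan oracle: thresholds recovering exactly 20 spots
        good = [th for th in np.linspace(1, 60, 300)
                if len(detect_spots(frame, DetectionParams(sigma_px=1.3,
                                                           threshold=th))) == 20]
        assert good, "oracle found no plateau"
        assert min(good) <= auto.threshold <= max(good)

    def test_hybrid_between_ingredients(self, rng):
        pos = rng.uniform(12, 116, size=(12, 2))
        frame = render_noiseless_frame(pos, rng.uniform(80, 120, 12), (128, 128), 1.3)
        frame = frame + rng.normal(150, 6, frame.shape)
        auto = auto_threshold([frame], sigma_px=1.3)
        lo = min(auto.elbow_threshold, auto.plateau_threshold)
        hi = max(auto.elbow_threshold, auto.plateau_threshold)
        assert lo <= auto.threshold <= hi

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            auto_threshold([], sigma_px=1.3)


class TestClusters:
    def _detect(self, frame, multiplier=2.0):
        params = DetectionParams(sigma_px=1.3, threshold=15.0,
                                 cluster_multiplier=multiplier)
        return detect_spots(frame, params), params

    def test_uniform_spots_not_flagged(self, rng):
        pos = rng.uniform(15, 110, size=(8, 2))
        frame = render_noiseless_frame(pos, np.full(8, 120.0), (128, 128), 1.3)
        spots, _ = self._detect(frame, multiplier=2.0)
        assert len(spots) == 8
        assert not spots["is_cluster"].any()

    def test_single_oversized_spot_flagged(self, rng):
        pos = np.array([[20.0, 20.0], [20.0, 60.0], [20.0, 100.0],
                        [60.0, 20.0], [60.0, 60.0], [60.0, 100.0],
                        [100.0, 40.0]])
        frame = render_noiseless_frame(pos[:-1], np.full(6, 120.0), (128, 128), 1.3)
        # one spot rendered 3x wider: a diffraction-breaking aggregate
        frame += render_noiseless_frame(pos[-1:], np.array([120.0]), (128, 128),
                                        3 * 1.3)
        spots, _ = self._detect(frame, multiplier=2.0)
        flagged = spots[spots["is_cluster"]]
        assert len(flagged) == 1
        assert abs(flagged.iloc[0]["y_px"] - 100.0) < 1.5
        assert abs(flagged.iloc[0]["x_px"] - 40.0) < 1.5

    def test_huge_multiplier_flags_nothing(self, rng):
        pos = rng.uniform(15, 110, size=(6, 2))
        frame = render_noiseless_frame(pos, rng.uniform(60, 200, 6), (128, 128), 1.3)
        frame += render_noiseless_frame(np.array([[64.0, 64.0]]), np.array([150.0]),
                                        (128, 128), 4.0)
        params = DetectionParams(sigma_px=1.3, threshold=15.0,
                                 cluster_multiplier=1e6)
        spots = detect_spots(frame, params)
        assert not spots["is_cluster"].any()

    def test_drop_option_removes_flagged(self, rng):
        frame = render_noiseless_frame(np.array([[30.0, 30.0]]), np.array([120.0]),
                                       (96, 96), 1.3)
        frame += render_noiseless_frame(np.array([[70.0, 70.0]]), np.array([120.0]),
                                        (96, 96), 3 * 1.3)
        params = DetectionParams(sigma_px=1.3, threshold=15.0, cluster_multiplier=2.0)
        spots = detect_spots(frame, params)
        kept = flag_clusters(spots, params, drop=True)
        assert len(kept) < len(spots)
        assert not kept["is_cluster"].any()


def test_scaled_benchmark_precision_and_recall(mini_benchmark):
    """Detection on the scaled benchmark movie recovers the simulated spots."""
    params, movie, truth = mini_benchmark
    sample = [movie.frame(t, 0) for t in np.linspace(0, movie.n_frames - 1, 8).astype(int)]
    auto = auto_threshold(sample, params.psf_sigma_px)
    det_params = DetectionParams(sigma_px=params.psf_sigma_px, threshold=auto.threshold)
    recalls, precisions = [], []
    for t in range(0, movie.n_frames, 4):
        spots = detect_spots(movie.frame(t, 0), det_params, frame=t)
        det = spots[["y_px", "x_px"]].to_numpy()
        gt = truth.positions_at(t)
        if len(det) == 0:
            recalls.append(0.0)
            continue
        d = np.linalg.norm(det[:, None, :] - gt[None, :, :], axis=2)
        recalls.append(np.mean(d.min(axis=0) <= 2.0))
        precisions.append(np.mean(d.min(axis=1) <= 2.0))
    assert np.mean(recalls) >= 0.9
    assert np.mean(precisions) >= 0.9
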