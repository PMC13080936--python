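import itertools

import numpy as np
import pandas as pd
import pytest

from livespot.tracking import (Track, compute_msd, estimate_diffusion,
                               link_multichannel, link_spots, tracks_to_table)


def spots_from_positions(positions_by_frame, channel=0):
    """Build a spot table from {frame: [(y, x), ...]}."""
    rows = []
    for frame in sorted(positions_by_frame):
        for y, x in positions_by_frame[frame]:
            rows.append({"frame": frame, "channel": channel, "y_px": y, "x_px": x})
    return pd.DataFrame(rows)


def exhaustive_link(positions_by_frame, max_disp):
    """Brute-force frame-to-frame linking oracle (no memory).

    Per consecutive frame pair, enumerates every gate-valid assignment and
    keeps the one with the most links, tie-broken by minimum total squared
    displacement (the nearest-neighbor objective: link whatever can be
    linked, as cheaply as possible). Links are chained into tracks.
    Returns (total squared displacement, tracks as (frame, y, x) tuples).
    """
    frames = sorted(positions_by_frame)

    def best_pair_assignment(prev_pts, next_pts):
        n_p, n_n = len(prev_pts), len(next_pts)
        best = (0, 0.0, {})
        for k in range(min(n_p, n_n) + 1):
            for rows in itertools.combinations(range(n_p), k):
                for cols in itertools.permutations(range(n_n), k):
                    cost = 0.0
                    ok = True
                    for r, c in zip(rows, cols):
                        d2 = (prev_pts[r][0] - next_pts[c][0]) ** 2 + \
                             (prev_pts[r][1] - next_pts[c][1]) ** 2
                        if d2 > max_disp**2:
                            ok = False
                            break
                        cost += d2
                    if ok and (k > best[0] or (k == best[0] and cost < best[1])):
                        best = (k, cost, dict(zip(rows, cols)))
        return best

    tracks = [[(frames[0], *p)] for p in positions_by_frame[frames[0]]]
    open_ids = list(range(len(tracks)))
    total = 0.0
    for prev_f, frame in zip(frames, frames[1:]):
        pts = positions_by_frame[frame]
        prev_pts = [tracks[i][-1][1:] for i in open_ids]
        _, cost, assign = best_pair_assignment(prev_pts, pts)
        total += cost
        new_open = []
        matched_next = set()
        for r, c in assign.items():
            tracks[open_ids[r]].append((frame, *pts[c]))
            new_open.append(open_ids[r])
            matched_next.add(c)
        for c in range(len(pts)):
            if c not in matched_next:
                tracks.append([(frame, *pts[c])])
                new_open.append(len(tracks) - 1)
        open_ids = new_open
    return total, [tuple(tr) for tr in tracks]


class TestLinking:
    def test_single_stationary_spot(self):
        pos = {f: [(10.0, 10.0)] for f in range(20)}
        tracks = link_spots(spots_from_positions(pos), max_disp_px=2.0,
                            memory=0, min_track_len=5)
        assert len(tracks) == 1
        assert tracks[0].n_points == 20
        assert len(tracks[0].gap_frames) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_particles, n_frames = 4, 5
        starts = rng.uniform(10, 90, size=(n_particles, 2))
        pos = {}
        walks = starts[:, None, :] + np.cumsum(
            rng.normal(0, 0.4, size=(n_particles, n_frames, 2)), axis=1)
        for f in range(n_frames):
            pts = [tuple(walks[i, f]) for i in range(n_particles)]
            rng.shuffle(pts)
            pos[f] = pts
        tracks = link_spots(spots_from_positions(pos), max_disp_px=3.0,
                            memory=0, min_track_len=1)
        cost_impl = sum(
            float(np.sum(np.diff(tr.positions, axis=0) ** 2)) for tr in tracks)
        cost_oracle, oracle_tracks = exhaustive_link(pos, max_disp=3.0)
        assert cost_impl == pytest.approx(cost_oracle, abs=1e-9)
        impl_sets = sorted(
            tuple((int(f), round(y, 6), round(x, 6))
                  for f, (y, x) in zip(tr.frames, tr.positions))
            for tr in tracks)
        oracle_sets = sorted(
            tuple((int(f), round(y, 6), round(x, 6)) for f, y, x in tr)
            for tr in oracle_tracks)
        assert impl_sets == oracle_sets

    def test_memory_semantics_across_one_missing_frame(self):
        pos = {f: [(20.0, 20.0)] for f in range(10) if f != 5}
        spots = spots_from_positions(pos)
        with_memory = link_spots(spots, max_disp_px=2.0, memory=1, min_track_len=1)
        assert len(with_memory) == 1
        assert list(with_memory[0].gap_frames) == [5]
        without = link_spots(spots, max_disp_px=2.0, memory=0, min_track_len=1)
        assert len(without) == 2

    def test_each_spot_in_at_most_one_track(self, rng):
        spots = spots_from_positions({
            f: [tuple(p) for p in rng.uniform(0, 100, size=(6, 2))]
            for f in range(8)
        })
        tracks = link_spots(spots, max_disp_px=30.0, memory=1, min_track_len=1)
        used = np.concatenate([tr.spot_indices for tr in tracks])
        assert len(used) == len(set(used))
        assert len(used) == len(spots)  # min_track_len=1 retains everything

    def test_translation_invariance(self, rng):
        base = {f: [tuple(p) for p in rng.uniform(20, 60, size=(3, 2))]
                for f in range(6)}
        shifted = {f: [(y + 500.0, x + 300.0) for y, x in pts]
                   for f, pts in base.items()}
        t1 = link_spots(spots_from_positions(base), 50.0, 0, 1)
        t2 = link_spots(spots_from_positions(shifted), 50.0, 0, 1)
        sig1 = sorted(tuple(tr.frames) for tr in t1)
        sig2 = sorted(tuple(tr.frames) for tr in t2)
        assert sig1 == sig2

    def test_assignment_beats_greedy_on_crossing(self):
        # two particles crossing: greedy locks the near pair, assignment
        # minimizes the total squared displacement
        pos = {0: [(10.0, 10.0), (10.0, 16.0)],
               1: [(10.0, 12.9), (10.0, 13.5)]}
        spots = spots_from_positions(pos)
        opt = link_spots(spots, 10.0, 0, 1, method="assignment")
        greedy = link_spots(spots, 10.0, 0, 1, method="greedy")

        def total_cost(tracks):
            return sum(float(np.sum(np.diff(tr.positions, axis=0) ** 2))
                       for tr in tracks)

        assert total_cost(opt) <= total_cost(greedy)
        oracle_cost, _ = exhaustive_link(pos, max_disp=10.0)
        assert total_cost(opt) == pytest.approx(oracle_cost, abs=1e-9)

    def test_min_track_len_filter(self):
        pos = {0: [(5.0, 5.0), (50.0, 50.0)], 1: [(5.1, 5.0)], 2: [(5.2, 5.0)]}
        tracks = link_spots(spots_from_positions(pos), 2.0, 0, min_track_len=3)
        assert len(tracks) == 1
        assert tracks[0].n_points == 3


class TestMultichannel:
    def test_identical_channels_disjoint_ids(self, rng):
        pts = {f: [tuple(p) for p in rng.uniform(10, 90, size=(3, 2))]
               for f in range(5)}
        spots = pd.concat([spots_from_positions(pts, channel=0),
                           spots_from_positions(pts, channel=1)],
                          ignore_index=True)
        params = {0: dict(max_disp_px=20.0, memory=0, min_track_len=1),
                  1: dict(max_disp_px=20.0, memory=0, min_track_len=1)}
        tracks = link_multichannel(spots, params)
        ids = [tr.track_id for tr in tracks]
        assert len(ids) == len(set(ids))
        geo0 = sorted(tuple(map(tuple, np.round(tr.positions, 6)))
                      for tr in tracks if tr.channel == 0)
        geo1 = sorted(tuple(map(tuple, np.round(tr.positions, 6)))
                      for tr in tracks if tr.channel == 1)
        assert geo0 == geo1

    def test_per_channel_params_match_single_channel_runs(self, rng):
        pts0 = {f: [tuple(p) for p in rng.uniform(10, 90, size=(2, 2))]
                for f in range(5)}
        pts1 = {f: [tuple(p) for p in rng.uniform(10, 90, size=(4, 2))]
                for f in range(5)}
        spots = pd.concat([spots_from_positions(pts0, 0),
                           spots_from_positions(pts1, 1)], ignore_index=True)
        params = {0: dict(max_disp_px=5.0, memory=0, min_track_len=1),
                  1: dict(max_disp_px=40.0, memory=1, min_track_len=2)}
        combined = link_multichannel(spots, params)
        for ch in (0, 1):
            solo = link_spots(spots[spots["channel"] == ch], **params[ch])
            combo = [tr for tr in combined if tr.channel == ch]
            assert sorted(tuple(tr.frames) for tr in combo) == \
                   sorted(tuple(tr.frames) for tr in solo)

    def test_empty_channel_yields_no_tracks(self):
        spots = spots_from_positions({0: [(1.0, 1.0)], 1: [(1.0, 1.0)]})
        params = {0: dict(max_disp_px=2.0, memory=0, min_track_len=1),
                  1: dict(max_disp_px=2.0, memory=0, min_track_len=1)}
        tracks = link_multichannel(spots, params)
        assert all(tr.channel == 0 for tr in tracks)

    def test_track_id_written_back(self):
        pos = {f: [(10.0, 10.0)] for f in range(12)}
        spots = spots_from_positions(pos)
        tracks = link_spots(spots, 2.0, 0, 10)
        table = tracks_to_table(spots, tracks)
        assert (table["track_id"] == 0).all()


class TestMsd:
    def _track(self, frames, positions):
        return Track(track_id=0, channel=0, frames=np.asarray(frames),
                     positions=np.asarray(positions, dtype=float),
                     spot_indices=np.arange(len(frames)))

    def test_stationary_msd_is_zero(self):
        tr = self._track(range(10), [(3.0, 4.0)] * 10)
        curve = compute_msd(tr, frame_interval_s=1.0)
        assert np.all(curve.msd_px2 == 0.0)

    def test_ballistic_quadratic(self):
        v = 1.0
        frames = np.arange(30)
        tr = self._track(frames, [(0.0, v * f) for f in frames])
        curve = compute_msd(tr, frame_interval_s=1.0, max_lag_frames=10)
        np.testing.assert_allclose(curve.msd_px2, (v * curve.lags_s) ** 2,
                                   rtol=1e-12)

    def test_gaps_excluded_pairwise(self):
        frames = [0, 1, 3, 4]
        tr = self._track(frames, [(0.0, f) for f in frames])
        curve = compute_msd(tr, frame_interval_s=2.0, max_lag_frames=2)
        assert curve.n_pairs[1] == 2  # (0,1) and (3,4)
        assert curve.lags_s[1] == 2.0

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(self._track([0], [(0.0, 0.0)]), 1.0)


class TestDiffusion:
    def _brownian_curves(self, d, n_tracks=100, n_frames=200, dt=1.0, seed=0):
        rng = np.random.default_rng(seed)
        curves = []
        for _ in range(n_tracks):
            steps = rng.normal(0, np.sqrt(2 * d * dt), size=(n_frames, 2))
            walk = np.cumsum(steps, axis=0)
            tr = Track(track_id=0, channel=0, frames=np.arange(n_frames),
                       positions=walk, spot_indices=np.arange(n_frames))
            curves.append(compute_msd(tr, dt, max_lag_frames=8))
        return curves

    def test_known_diffusion_recovered_within_ci(self):
        d_true = 0.05
        curves = self._brownian_curves(d_true)
        d_hat, (lo, hi) = estimate_diffusion(curves, n_fit_lags=4,
                                             rng=np.random.default_rng(1))
        assert lo <= d_true <= hi
        assert d_hat == pytest.approx(d_true, rel=0.2)

    def test_stationary_ensemble_gives_zero(self):
        curves = []
        for _ in range(10):
            tr = Track(track_id=0, channel=0, frames=np.arange(50),
                       positions=np.full((50, 2), 7.0),
                       spot_indices=np.arange(50))
            curves.append(compute_msd(tr, 1.0, max_lag_frames=8))
        d_hat, _ = estimate_diffusion(curves, rng=np.random.default_rng(0))
        assert d_hat == 0.0

    def test_frame_interval_units(self):
        d_true = 0.05
        curves_1s = self._brownian_curves(d_true, dt=1.0, seed=5)
        rng = np.random.default_rng(9)
        d1, _ = estimate_diffusion(curves_1s, rng=rng)
        # same pixel trajectories with doubled frame interval
        rng2 = np.random.default_rng(5)
        curves_2s = []
        for _ in range(100):
            steps = rng2.normal(0, np.sqrt(2 * d_true), size=(200, 2))
            walk = np.cumsum(steps, axis=0)
            tr = Track(track_id=0, channel=0, frames=np.arange(200),
                       positions=walk, spot_indices=np.arange(200))
            curves_2s.append(compute_msd(tr, 2.0, max_lag_frames=8))
        d2, _ = estimate_diffusion(curves_2s, rng=np.random.default_rng(9))
        assert d2 == pytest.approx(d1 / 2, rel=1e-9)
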