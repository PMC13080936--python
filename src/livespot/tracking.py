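"""Link per-frame detections into trajectories; MSD and diffusion estimation.

Linking is frame-to-frame optimal bipartite assignment (minimum total
squared displacement) gated at a maximum displacement, the deterministic
member of the nearest-neighbor family; a greedy variant is available for
comparison. Track heads that miss a detection persist as candidates for
up to ``memory`` frames with a search radius that grows linearly with the
gap length.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Track",
    "MsdCurve",
    "link_spots",
    "link_multichannel",
    "tracks_to_table",
    "compute_msd",
    "estimate_diffusion",
]


@dataclasses.dataclass
class Track:
    """One linked trajectory within a single channel."""

    track_id: int
    channel: int
    frames: np.ndarray        # strictly increasing detection frames
    positions: np.ndarray     # (n, 2) as (y, x)
    spot_indices: np.ndarray  # row indices into the source spot table

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.spot_indices = np.asarray(self.spot_indices, dtype=int)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def gap_frames(self) -> np.ndarray:
        """Frames inside the track span with no detection (bridged by memory)."""
        full = np.arange(self.frames[0], self.frames[-1] + 1)
        return np.setdiff1d(full, self.frames)


@dataclasses.dataclass
class MsdCurve:
    lags_s: np.ndarray
    msd_px2: np.ndarray
    n_pairs: np.ndarray
    diffusion_px2s: float | None = None
    intercept_px2: float | None = None
    fit_r2: float | None = None


def _assign(cost: np.ndarray, gates: np.ndarray, method: str) -> list[tuple[int, int]]:
    """Gated assignment between track heads (rows) and detections (cols)."""
    big = 1e12
    masked = np.where(gates, cost, big)
    pairs: list[tuple[int, int]] = []
    if method == "assignment":
        # pad to square implicitly: linear_sum_assignment handles rectangles
        rows, cols = linear_sum_assignment(masked)
        for r, c in zip(rows, cols):
            if gates[r, c]:
                pairs.append((r, c))
    elif method == "greedy":
        taken_r: set[int] = set()
        taken_c: set[int] = set()
        order = np.argsort(masked, axis=None)
        for flat in order:
            r, c = np.unravel_index(flat, masked.shape)
            if masked[r, c] >= big:
                break
            if r in taken_r or c in taken_c:
                continue
            pairs.append((int(r), int(c)))
            taken_r.add(int(r))
            taken_c.add(int(c))
    else:
        raise ValueError("method must be 'assignment' or 'greedy'")
    return pairs


def link_spots(spots: pd.DataFrame, max_disp_px: float, memory: int = 0,
               min_track_len: int = 10, method: str = "assignment") -> list[Track]:
    """Link a single-channel spot table into tracks.

    Per frame, detections are matched to open track heads by minimum total
    squared displacement among pairs within the gated radius
    ``max_disp_px * (gap + 1)``; unmatched heads stay open for up to
    ``memory`` frames. Tracks with fewer than ``min_track_len`` detections
    are discarded. Each spot belongs to at most one track.
    """
    if max_disp_px < 0 or memory < 0 or min_track_len < 0:
        raise ValueError("linking parameters must be >= 0")
    if len(spots) == 0:
        return []
    if spots["channel"].nunique() > 1:
        raise ValueError("link_spots expects a single channel; use link_multichannel")
    channel = int(spots["channel"].iloc[0])
    frames = np.sort(spots["frame"].unique())
    # open track state: list of dicts
    open_tracks: list[dict] = []
    done_tracks: list[dict] = []
    for f in frames:
        sub = spots[spots["frame"] == f]
        det_pos = sub[["y_px", "x_px"]].to_numpy(dtype=float)
        det_idx = sub.index.to_numpy()
        n_det = len(sub)
        matched_det = np.zeros(n_det, dtype=bool)
        # retire heads whose gap already exceeds the memory before matching
        still_open = []
        for tr in open_tracks:
            if f - tr["frames"][-1] - 1 > memory:
                done_tracks.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        if open_tracks and n_det:
            head_pos = np.array([tr["positions"][-1] for tr in open_tracks])
            gaps = np.array([f - tr["frames"][-1] - 1 for tr in open_tracks])
            diff = head_pos[:, None, :] - det_pos[None, :, :]
            cost = np.sum(diff**2, axis=2)
            radii = max_disp_px * (gaps + 1)
            gates = cost <= (radii[:, None] ** 2)
            for r, c in _assign(cost, gates, method):
                tr = open_tracks[r]
                tr["frames"].append(int(f))
                tr["positions"].append(det_pos[c])
                tr["spot_indices"].append(int(det_idx[c]))
                matched_det[c] = True
        # new tracks from unmatched detections
        for c in np.where(~matched_det)[0]:
            open_tracks.append({
                "frames": [int(f)],
                "positions": [det_pos[c]],
                "spot_indices": [int(det_idx[c])],
            })
    done_tracks.extend(open_tracks)
    tracks = []
    next_id = 0
    # deterministic order: by first frame, then first position
    done_tracks.sort(key=lambda tr: (tr["frames"][0], tr["positions"][0][0], tr["positions"][0][1]))
    for tr in done_tracks:
        if len(tr["frames"]) < min_track_len:
            continue
        tracks.append(Track(
            track_id=next_id, channel=channel,
            frames=np.array(tr["frames"]),
            positions=np.array(tr["positions"]),
            spot_indices=np.array(tr["spot_indices"]),
        ))
        next_id += 1
    return tracks


def link_multichannel(spots: pd.DataFrame, per_channel_params: dict[int, dict]) -> list[Track]:
    """Independently link each channel; track ids are unique across channels."""
    tracks: list[Track] = []
    offset = 0
    for channel in sorted(per_channel_params):
        sub = spots[spots["channel"] == channel]
        ch_tracks = link_spots(sub, **per_channel_params[channel])
        for tr in ch_tracks:
            tr.track_id += offset
        tracks.extend(ch_tracks)
        offset += len(ch_tracks)
    return tracks


def tracks_to_table(spots: pd.DataFrame, tracks: list[Track]) -> pd.DataFrame:
    """Fill ``track_id`` in a spot table from a set of tracks."""
    spots = spots.copy()
    spots["track_id"] = np.nan
    for tr in tracks:
        spots.loc[tr.spot_indices, "track_id"] = tr.track_id
    return spots


def compute_msd(track: Track, frame_interval_s: float,
                max_lag_frames: int | None = None) -> MsdCurve:
    """Time-averaged mean squared displacement of one track.

    Pairs separated by exactly ``k`` frames contribute to lag ``k``; gap
    frames simply produce no pairs at the affected lags.
    """
    if track.n_points < 2:
        raise ValueError("MSD needs a track with at least 2 points")
    span = int(track.frames[-1] - track.frames[0])
    max_lag = span if max_lag_frames is None else min(max_lag_frames, span)
    frame_index = {int(f): i for i, f in enumerate(track.frames)}
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    n_pairs = np.zeros(max_lag + 1, dtype=int)
    for k in lags[1:]:
        total = 0.0
        count = 0
        for f, i in frame_index.items():
            j = frame_index.get(f + int(k))
            if j is not None:
                d = track.positions[j] - track.positions[i]
                total += float(d @ d)
                count += 1
        if count:
            msd[k] = total / count
            n_pairs[k] = count
    n_pairs[0] = track.n_points
    return MsdCurve(lags_s=lags * frame_interval_s, msd_px2=msd, n_pairs=n_pairs)


def estimate_diffusion(curves: list[MsdCurve], n_fit_lags: int = 4,
                       n_boot: int = 200,
                       rng: np.random.Generator | None = None) -> tuple[float, tuple[float, float]]:
    """Ensemble diffusion coefficient from MSD curves.

    Fits ``msd = 4 D tau + b`` by weighted least squares over the first
    ``n_fit_lags`` nonzero lags of the pair-weighted ensemble mean curve;
    D is clamped at 0. The confidence interval is a 2.5–97.5% bootstrap
    over tracks.
    """
    usable = [c for c in curves if len(c.lags_s) > n_fit_lags]
    if not usable:
        raise ValueError(f"no MSD curve has at least {n_fit_lags} lags")

    def fit(curve_set: list[MsdCurve]) -> float:
        lags = usable[0].lags_s[1:n_fit_lags + 1]
        num = np.zeros(n_fit_lags)
        den = np.zeros(n_fit_lags)
        for c in curve_set:
            w = c.n_pairs[1:n_fit_lags + 1]
            num += c.msd_px2[1:n_fit_lags + 1] * w
            den += w
        mean_msd = num / np.maximum(den, 1)
        coeffs = np.polyfit(lags, mean_msd, 1, w=np.sqrt(np.maximum(den, 1)))
        return max(float(coeffs[0]) / 4.0, 0.0)

    d_hat = fit(usable)
    rng = np.random.default_rng(0) if rng is None else rng
    boots = []
    for _ in range(n_boot):
        sample = [usable[i] for i in rng.integers(0, len(usable), size=len(usable))]
        boots.append(fit(sample))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return d_hat, (float(lo), float(hi))
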