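"""Two-channel colocalization by distance-gated one-to-one assignment.

A translation site is one mRNA plus one nascent-protein signal, so
matching is one-to-one (minimum total distance) rather than
all-neighbors counting. Track-level colocalization summarizes the
per-frame matches as the fraction of co-resolved frames within the
distance gate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .tracking import Track

__all__ = ["ColocPair", "match_spots_frame", "colocalize_tracks", "pairs_to_table"]

#: Default gate: about one PSF sigma plus localization error.
DEFAULT_D_MAX_PX = 2.0


@dataclasses.dataclass
class ColocPair:
    id_a: int
    id_b: int
    distance_px: float              # per-frame distance, or mean distance for tracks
    frame: int | None = None        # None for track-level pairs
    fraction: float | None = None   # colocalized fraction for track-level pairs


def match_spots_frame(spots_a: pd.DataFrame, spots_b: pd.DataFrame,
                      d_max_px: float = DEFAULT_D_MAX_PX
                      ) -> tuple[list[ColocPair], np.ndarray, np.ndarray]:
    """One-to-one minimum-total-distance matching within one frame.

    Returns the matched pairs plus the (index) arrays of unmatched spots
    in each channel. Pairs farther apart than ``d_max_px`` are forbidden.
    """
    pos_a = spots_a[["y_px", "x_px"]].to_numpy(dtype=float)
    pos_b = spots_b[["y_px", "x_px"]].to_numpy(dtype=float)
    idx_a = spots_a.index.to_numpy()
    idx_b = spots_b.index.to_numpy()
    if len(pos_a) == 0 or len(pos_b) == 0:
        return [], idx_a, idx_b
    dist = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    gates = dist <= d_max_px
    big = 1e12
    rows, cols = linear_sum_assignment(np.where(gates, dist, big))
    frame = int(spots_a["frame"].iloc[0]) if "frame" in spots_a and len(spots_a) else None
    pairs = []
    matched_a, matched_b = set(), set()
    for r, c in zip(rows, cols):
        if gates[r, c]:
            pairs.append(ColocPair(id_a=int(idx_a[r]), id_b=int(idx_b[c]),
                                   distance_px=float(dist[r, c]), frame=frame))
            matched_a.add(r)
            matched_b.add(c)
    un_a = idx_a[[i for i in range(len(idx_a)) if i not in matched_a]]
    un_b = idx_b[[i for i in range(len(idx_b)) if i not in matched_b]]
    return pairs, un_a, un_b


def colocalize_tracks(tracks_a: list[Track], tracks_b: list[Track],
                      d_max_px: float = DEFAULT_D_MAX_PX,
                      min_fraction: float = 0.5) -> list[ColocPair]:
    """Pair tracks across channels by their per-frame proximity.

    For each candidate pair, ``fraction`` is the share of co-resolved
    frames (frames where both tracks have a detection) at distance
    <= ``d_max_px``. Pairs reaching ``min_fraction`` are reported; each
    track joins at most one pair — higher fraction wins, ties broken by
    smaller mean distance.
    """
    candidates = []
    for a in tracks_a:
        fa = {int(f): i for i, f in enumerate(a.frames)}
        for b in tracks_b:
            common = [(fa[int(f)], j) for j, f in enumerate(b.frames) if int(f) in fa]
            if not common:
                continue
            d = np.array([np.linalg.norm(a.positions[i] - b.positions[j])
                          for i, j in common])
            fraction = float(np.mean(d <= d_max_px))
            if fraction >= min_fraction:
                candidates.append((fraction, float(d.mean()), a.track_id, b.track_id))
    # best-first selection, each track used once
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    used_a, used_b = set(), set()
    pairs = []
    for fraction, mean_d, ida, idb in candidates:
        if ida in used_a or idb in used_b:
            continue
        pairs.append(ColocPair(id_a=ida, id_b=idb, distance_px=mean_d,
                               fraction=fraction))
        used_a.add(ida)
        used_b.add(idb)
    return pairs


def pairs_to_table(pairs: list[ColocPair], method: str = "distance") -> pd.DataFrame:
    rows = [{
        "frame": p.frame if p.frame is not None else np.nan,
        "id_a": p.id_a,
        "id_b": p.id_b,
        "distance_px": p.distance_px,
        "fraction": p.fraction if p.fraction is not None else np.nan,
        "method": method,
    } for p in pairs]
    return pd.DataFrame(rows, columns=["frame", "id_a", "id_b", "distance_px",
                                       "fraction", "method"])
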