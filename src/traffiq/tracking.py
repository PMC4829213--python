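"""Fast-mode single-particle tracking: linking, speed, MSD classification.

Spots detected in sub-second-cadence movies are linked frame to frame by a
deterministic greedy mutual-nearest-neighbour rule with one-frame gap
closing, then summarized per track:

* mean speed — mean per-step |dx|/dt over steps above a noise floor (twice
  the localization error by default), so a stationary spot jittering by
  its localization precision reports zero rather than a spurious drift;
* motion class — the MSD power-law exponent alpha fitted over the first
  quarter of available lags: alpha >= 1.3 directed, alpha <= 0.7
  confined, diffusive in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Track", "link_tracks", "track_speed", "classify_motion", "msd_alpha",
    "DIRECTED_ALPHA", "CONFINED_ALPHA",
]

DIRECTED_ALPHA = 1.3
CONFINED_ALPHA = 0.7


@dataclass
class Track:
    """One linked trajectory: times in seconds, positions in micrometres."""

    t_s: np.ndarray
    xy_um: np.ndarray            # (n, 2)
    frames: np.ndarray
    mean_speed: float = float("nan")
    stationary: bool = False
    msd_alpha: float = float("nan")
    motion_class: str = "unclassified"

    def __len__(self) -> int:
        return len(self.t_s)


def _mutual_nn_pairs(a: np.ndarray, b: np.ndarray, max_disp: float):
    """Greedy mutual-nearest-neighbour pairs (i, j) under ``max_disp``.

    Candidate pairs are taken in order of increasing distance, ties broken
    by (i, j) index, each endpoint used at most once — deterministic for a
    given input order.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    tree = cKDTree(b)
    dists, idx = tree.query(a, k=min(len(b), 4), distance_upper_bound=max_disp)
    dists = np.atleast_2d(dists.T).T
    idx = np.atleast_2d(idx.T).T
    cand = []
    for i in range(len(a)):
        for d, j in zip(dists[i], idx[i]):
            if np.isfinite(d) and j < len(b):
                cand.append((float(d), i, int(j)))
    cand.sort()
    used_a, used_b, pairs = set(), set(), []
    for d, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def link_tracks(
    per_frame_spots,
    times_s,
    max_disp_um: float = 1.5,
    max_gap_frames: int = 1,
) -> list[Track]:
    """Link per-frame spot positions (um) into trajectories.

    ``per_frame_spots`` is a sequence of (n_i, 2) arrays.  Spots link to
    the nearest mutual neighbour within ``max_disp_um`` in the next frame;
    tracks missing a detection may bridge up to ``max_gap_frames`` frames
    (with a proportionally larger search radius).  Unmatched spots start
    new tracks.
    """
    per_frame_spots = [np.asarray(s, dtype=float).reshape(-1, 2) for s in per_frame_spots]
    times_s = np.asarray(times_s, dtype=float)
    if len(per_frame_spots) < 2:
        raise ValueError("need at least two frames of detections")

    # active track state: list of dicts with last frame, last position, rows
    active: list[dict] = []
    finished: list[dict] = []

    def start(fi, pt):
        active.append({"frames": [fi], "pts": [pt]})

    for pt in per_frame_spots[0]:
        start(0, pt)

    for fi in range(1, len(per_frame_spots)):
        spots = per_frame_spots[fi]
        unmatched = set(range(len(spots)))
        # try gaps of 0..max_gap in order, nearest links first at each gap
        for gap in range(0, max_gap_frames + 1):
            cands = [
                k for k, tr in enumerate(active)
                if fi - tr["frames"][-1] == gap + 1
            ]
            if not cands or not unmatched:
                continue
            a = np.array([active[k]["pts"][-1] for k in cands])
            open_idx = sorted(unmatched)
            b = spots[open_idx]
            pairs = _mutual_nn_pairs(a, b, max_disp_um * (gap + 1))
            for i, j in pairs:
                k = cands[i]
                sj = open_idx[j]
                active[k]["frames"].append(fi)
                active[k]["pts"].append(spots[sj])
                unmatched.discard(sj)
        # retire tracks that exceeded the allowed gap
        still = []
        for tr in active:
            if fi - tr["frames"][-1] > max_gap_frames:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        for sj in sorted(unmatched):
            start(fi, spots[sj])

    finished.extend(active)
    tracks = []
    for tr in finished:
        fr = np.asarray(tr["frames"])
        tracks.append(
            Track(
                t_s=times_s[fr],
                xy_um=np.asarray(tr["pts"]),
                frames=fr,
            )
        )
    return tracks


def track_speed(track: Track, noise_floor_um: float = 0.05) -> Track:
    """Mean per-step speed (um/s) over steps longer than the noise floor.

    Requires at least 5 points.  If no step clears the floor the track is
    flagged stationary with speed 0.
    """
    if len(track) < 5:
        raise ValueError("track_speed requires at least 5 points")
    steps = np.diff(track.xy_um, axis=0)
    dt = np.diff(track.t_s)
    d = np.hypot(steps[:, 0], steps[:, 1])
    keep = d > noise_floor_um
    if not keep.any():
        track.mean_speed = 0.0
        track.stationary = True
        return track
    track.mean_speed = float(np.mean(d[keep] / dt[keep]))
    track.stationary = False
    return track


def msd_alpha(track: Track) -> float:
    """MSD power-law exponent over lags 1..floor(n/4)."""
    n = len(track)
    if n < 10:
        raise ValueError("msd_alpha requires at least 10 points")
    max_lag = max(n // 4, 2)
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    for li, lag in enumerate(lags):
        d = track.xy_um[lag:] - track.xy_um[:-lag]
        msd[li] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    if np.any(msd <= 0):
        return 0.0  # degenerate: zero-variance track
    dt = np.median(np.diff(track.t_s))
    slope, _ = np.polyfit(np.log(lags * dt), np.log(msd), 1)
    return float(slope)


def classify_motion(track: Track) -> Track:
    """Directed / diffusive / confined call from the MSD exponent."""
    alpha = msd_alpha(track)
    track.msd_alpha = alpha
    if alpha >= DIRECTED_ALPHA:
        track.motion_class = "directed"
    elif alpha <= CONFINED_ALPHA:
        track.motion_class = "confined"
    else:
        track.motion_class = "diffusive"
    return track
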