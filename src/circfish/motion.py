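"""Single-particle tracking and MSD diffusion analysis.

Detections from single-plane live imaging are linked frame to frame by
mutual nearest neighbors, tracks longer than five frames are kept, and
each track's diffusion coefficient comes from a weighted linear fit of
the time-averaged mean squared displacement over the first seven lags:

    MSD(k dt) = 4 D (k dt) + b        (2D; b = 4 sigma_loc^2 absorbs
                                       localization noise)

Tracks with D > 0.01 um^2/s are classified as freely diffusing, the rest
as confined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Track",
    "DiffusionEstimate",
    "link_detections",
    "filter_tracks",
    "compute_msd",
    "estimate_diffusion",
    "classify_mobility",
    "analyze_tracks",
    "tracks_from_table",
]

MIN_TRACK_FRAMES = 6       # "longer than five frames"
MAX_MSD_LAG = 7            # "first seven displacements"
FREE_D_THRESHOLD = 0.01    # um^2/s; free iff strictly greater


@dataclass
class Track:
    """Time-ordered 2D positions (nm) of one particle."""

    track_id: int
    frames: np.ndarray
    xy_nm: np.ndarray
    dt_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy_nm = np.asarray(self.xy_nm, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class DiffusionEstimate:
    track_id: int
    D_um2_s: float
    intercept_um2: float
    lags_used: int
    mobility: str
    clamped: bool = False


def tracks_from_table(table: pd.DataFrame, dt_s: float) -> list[Track]:
    """Build Track objects from a table with track_id, frame, x_nm, y_nm."""
    out = []
    for tid, grp in table.groupby("track_id"):
        grp = grp.sort_values("frame")
        out.append(Track(int(tid), grp["frame"].to_numpy(),
                         grp[["x_nm", "y_nm"]].to_numpy(), dt_s))
    return out


def link_detections(detections: pd.DataFrame,
                    dt_s: float,
                    max_disp_nm: float,
                    max_gap: int = 0) -> list[Track]:
    """Greedy mutual-nearest-neighbor frame-to-frame linking.

    ``detections`` needs columns ``frame, x_nm, y_nm``.  Between
    consecutive occupied frames, detections are paired when each is the
    other's nearest neighbor within ``max_disp_nm`` (scaled by the frame
    gap); unmatched detections start new tracks.  Track ends may bridge
    up to ``max_gap`` missing frames.
    """
    if len(detections) == 0:
        return []
    frames = sorted(detections["frame"].unique())
    by_frame = {f: detections[detections["frame"] == f][["x_nm", "y_nm"]]
                .to_numpy(dtype=float) for f in frames}
    # open tracks: list of dicts with frames list, points list
    open_tracks: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for f in frames:
        pts = by_frame[f]
        # candidates: open tracks whose last frame is within gap+1
        cand = [t for t in open_tracks if 1 <= f - t["frames"][-1] <= max_gap + 1]
        if cand and len(pts):
            last = np.array([t["xy"][-1] for t in cand])
            tree_pts = cKDTree(pts)
            tree_last = cKDTree(last)
            d_tp, nn_tp = tree_pts.query(last)   # per track: nearest detection
            d_pt, nn_pt = tree_last.query(pts)   # per detection: nearest track
            claimed = set()
            for ti, t in enumerate(cand):
                pi = nn_tp[ti]
                gap = f - t["frames"][-1]
                if (nn_pt[pi] == ti and pi not in claimed
                        and d_tp[ti] <= max_disp_nm * gap):
                    t["frames"].append(f)
                    t["xy"].append(pts[pi])
                    claimed.add(pi)
            new_idx = [i for i in range(len(pts)) if i not in claimed]
        else:
            new_idx = list(range(len(pts)))
        # retire tracks that fell outside the gap window
        still_open = []
        for t in open_tracks:
            (done if f - t["frames"][-1] > max_gap + 1 else still_open).append(t)
        open_tracks = still_open
        for i in new_idx:
            open_tracks.append({"id": next_id, "frames": [f], "xy": [pts[i]]})
            next_id += 1
    done.extend(open_tracks)
    done.sort(key=lambda t: t["id"])
    return [Track(t["id"], np.array(t["frames"]), np.array(t["xy"]), dt_s)
            for t in done]


def filter_tracks(tracks: list[Track],
                  min_frames: int = MIN_TRACK_FRAMES) -> list[Track]:
    """Keep tracks longer than five frames (n_frames >= 6 by default)."""
    return [t for t in tracks if t.n_frames >= min_frames]


def compute_msd(track: Track, max_lag: int = MAX_MSD_LAG) -> pd.DataFrame:
    """Time-averaged MSD over all start points, lags 1..min(max_lag, n-1).

    Returns columns ``lag, tau_s, msd_um2, n_pairs``; displacements are
    averaged over every ordered pair of positions ``lag`` frames apart.
    Assumes gap-free tracks (consecutive frames).
    """
    n = track.n_frames
    xy_um = track.xy_nm / 1000.0
    lags = np.arange(1, min(max_lag, n - 1) + 1)
    rows = []
    for k in lags:
        disp = xy_um[k:] - xy_um[:-k]
        sq = np.sum(disp**2, axis=1)
        rows.append({"lag": int(k), "tau_s": k * track.dt_s,
                     "msd_um2": float(np.mean(sq)), "n_pairs": int(len(sq))})
    return pd.DataFrame(rows)


def estimate_diffusion(msd: pd.DataFrame, dt_s: float,
                       track_id: int = -1,
                       free_intercept: bool = True) -> DiffusionEstimate:
    """Weighted linear fit ``MSD(tau) = 4 D tau + b`` (2D).

    Weights are proportional to the number of displacement pairs per
    lag, the leading-order variance structure of the time-averaged MSD.
    The free intercept absorbs localization noise (b = 4 sigma_loc^2),
    which would otherwise bias D upward.  A negative fitted D is clamped
    to zero and flagged.
    """
    if len(msd) < 2:
        raise ValueError("need at least 2 MSD lags to fit a line")
    tau = msd["tau_s"].to_numpy(dtype=float)
    y = msd["msd_um2"].to_numpy(dtype=float)
    w = msd["n_pairs"].to_numpy(dtype=float)
    if free_intercept:
        X = np.column_stack([tau, np.ones_like(tau)])
    else:
        X = tau[:, None]
    sw = np.sqrt(w)
    coef, _, _, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    slope = coef[0]
    intercept = float(coef[1]) if free_intercept else 0.0
    D = slope / 4.0
    clamped = D < 0
    if clamped:
        D = 0.0
    mobility = classify_mobility(D)
    return DiffusionEstimate(track_id, float(D), intercept,
                             lags_used=len(msd), mobility=mobility,
                             clamped=bool(clamped))


def classify_mobility(D_um2_s: float,
                      threshold: float = FREE_D_THRESHOLD) -> str:
    """"free" iff D strictly exceeds 0.01 um^2/s, else "confined"."""
    if D_um2_s < 0:
        raise ValueError("D must be >= 0")
    return "free" if D_um2_s > threshold else "confined"


def analyze_tracks(tracks: list[Track],
                   dt_s: float,
                   min_frames: int = MIN_TRACK_FRAMES,
                   max_lag: int = MAX_MSD_LAG,
                   free_intercept: bool = True) -> pd.DataFrame:
    """Filter, MSD, and diffusion fit for a track population.

    Returns one row per retained track: ``track_id, n_frames, D_um2_s,
    intercept_um2, lags_used, mobility, clamped``.
    """
    rows = []
    for t in filter_tracks(tracks, min_frames=min_frames):
        msd = compute_msd(t, max_lag=max_lag)
        est = estimate_diffusion(msd, dt_s, track_id=t.track_id,
                                 free_intercept=free_intercept)
        rows.append({"track_id": t.track_id, "n_frames": t.n_frames,
                     "D_um2_s": est.D_um2_s, "intercept_um2": est.intercept_um2,
                     "lags_used": est.lags_used, "mobility": est.mobility,
                     "clamped": est.clamped})
    return pd.DataFrame(rows, columns=["track_id", "n_frames", "D_um2_s",
                                       "intercept_um2", "lags_used",
                                       "mobility", "clamped"])
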