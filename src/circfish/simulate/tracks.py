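"""Synthetic 2D Brownian trajectories with localization noise.

Matches single-plane live-cell RNA tracking: per-axis displacements over
one frame interval are iid Normal(0, 2 D dt); reported positions carry
Gaussian localization error.  Ground truth is the generative D per track.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_tracks"]


def simulate_tracks(D_um2_s: float,
                    dt_s: float,
                    n_frames: int,
                    n_tracks: int,
                    noise_sd_nm: float = 0.0,
                    seed: int = 0,
                    field_um: float = 50.0) -> pd.DataFrame:
    """Brownian tracks and their per-frame detection table.

    Parameters
    ----------
    D_um2_s : diffusion coefficient in um^2/s (>= 0).
    dt_s : frame interval in seconds.
    n_frames : frames per track (>= 2).
    noise_sd_nm : localization error sd per axis, nm.
    field_um : track origins are spread over this square field.

    Returns
    -------
    DataFrame with columns ``track_id, frame, x_nm, y_nm, true_D`` —
    usable directly as a detection table (drop ``track_id``) or as
    ground-truth linked tracks.
    """
    if D_um2_s < 0:
        raise ValueError("D must be >= 0")
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    step_sd_nm = np.sqrt(2.0 * D_um2_s * dt_s) * 1000.0
    frames = np.arange(n_frames)
    out = []
    origins = rng.uniform(0.0, field_um * 1000.0, size=(n_tracks, 2))
    for tid in range(n_tracks):
        steps = rng.normal(0.0, step_sd_nm, size=(n_frames - 1, 2)) if step_sd_nm > 0 \
            else np.zeros((n_frames - 1, 2))
        pos = origins[tid] + np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        if noise_sd_nm > 0:
            pos = pos + rng.normal(0.0, noise_sd_nm, size=pos.shape)
        out.append(pd.DataFrame({
            "track_id": tid,
            "frame": frames,
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "true_D": D_um2_s,
        }))
    return pd.concat(out, ignore_index=True)
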