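"""Synthetic multi-spectral bead fields for chromatic calibration."""

from __future__ import annotations

import numpy as np

from ..registration import AffineTransform

__all__ = ["simulate_bead_field"]


def simulate_bead_field(true_transform: AffineTransform,
                        n_beads: int,
                        noise_sd_nm: float = 0.0,
                        field_nm: tuple[float, float, float] = (40000.0, 40000.0, 6000.0),
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Paired bead coordinates in two channels.

    Reference positions are uniform over a field centered on the optical
    axis (coordinates span +/- field/2, the frame in which the affine
    parameters decouple); moving positions are the true affine image of
    the reference plus iid Gaussian localization noise per axis.  Needs
    >= d+1 beads for downstream solvability.

    Returns ``(reference, moving)`` as (n, d) arrays in nm.
    """
    d = true_transform.ndim
    if n_beads < d + 1:
        raise ValueError(f"need at least {d + 1} beads for a {d}-D affine calibration")
    rng = np.random.default_rng(seed)
    half = np.asarray(field_nm[:d]) / 2.0
    ref = rng.uniform(-half, half, size=(n_beads, d))
    mov = true_transform.apply(ref)
    if noise_sd_nm > 0:
        mov = mov + rng.normal(0.0, noise_sd_nm, size=mov.shape)
    return ref, mov
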