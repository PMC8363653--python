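"""Synthetic SunTag translation-site fields (coordinate level).

Emulates the smFISH+IF readout: cytoplasmic intron molecules, a pool of
mature single SunTag proteins, and at a chosen fraction of introns a
nascent-peptide spot whose intensity is (number of ribosome-borne
peptides) x (single mature protein intensity).  Produced as spot tables,
the form the translation-site caller consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_translation_field"]


def simulate_translation_field(n_introns: int,
                               translating_fraction: float,
                               protein_unit: float = 1000.0,
                               occupancy: str | float = "poisson2plus1",
                               n_mature: int = 100,
                               mature_cv: float = 0.1,
                               site_cv: float = 0.05,
                               site_offset_sd_nm: float = 50.0,
                               field_um: float = 150.0,
                               min_sep_nm: float = 1500.0,
                               seed: int = 0,
                               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spot tables for translation-site calling with known ground truth.

    Parameters
    ----------
    occupancy : nascent-peptide count per translating intron.  The default
        ``"poisson2plus1"`` draws ``1 + Poisson(2)`` (every translating
        site carries at least one peptide, mean 3); a float gives a fixed
        count.
    site_cv : multiplicative intensity scatter of translation-site spots.
    mature_cv : intensity scatter of single mature proteins around the unit.

    Returns
    -------
    (introns, proteins, truth): ``introns`` has columns
    ``x_nm, y_nm, z_nm``; ``proteins`` adds ``integrated``; ``truth`` has
    one row per intron with ``translating`` and ``peptides``.
    """
    if not 0.0 <= translating_fraction <= 1.0:
        raise ValueError("translating_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    extent = field_um * 1000.0
    pos = _spread_positions(n_introns + n_mature, extent, min_sep_nm, rng)
    intron_pos = pos[:n_introns]
    mature_pos = pos[n_introns:]

    translating = rng.uniform(size=n_introns) < translating_fraction
    if occupancy == "poisson2plus1":
        peptides = np.where(translating, 1 + rng.poisson(2.0, size=n_introns), 0).astype(float)
    else:
        peptides = np.where(translating, float(occupancy), 0.0)

    introns = pd.DataFrame(intron_pos, columns=["x_nm", "y_nm", "z_nm"])
    prot_rows = []
    for i in np.nonzero(translating)[0]:
        offset = rng.normal(0.0, site_offset_sd_nm, size=3)
        inten = peptides[i] * protein_unit
        if site_cv > 0:
            inten *= max(rng.normal(1.0, site_cv), 0.05)
        prot_rows.append([*(intron_pos[i] + offset), inten])
    for j in range(n_mature):
        inten = protein_unit
        if mature_cv > 0:
            inten *= max(rng.normal(1.0, mature_cv), 0.05)
        prot_rows.append([*mature_pos[j], inten])
    proteins = pd.DataFrame(prot_rows, columns=["x_nm", "y_nm", "z_nm", "integrated"])
    truth = pd.DataFrame({"translating": translating, "peptides": peptides})
    return introns, proteins, truth


def _spread_positions(n: int, extent_nm: float, min_sep_nm: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform 3D positions with a guaranteed pairwise separation."""
    cell = min_sep_nm * 1.5
    per_side = int(extent_nm // cell)
    if per_side**2 < n:
        raise ValueError("field too small for the requested spot count")
    idx = rng.choice(per_side**2, size=n, replace=False)
    iy, ix = np.divmod(idx, per_side)
    jitter = rng.uniform(0.1, 0.9, size=(n, 2))
    x = (ix + jitter[:, 0]) * cell
    y = (iy + jitter[:, 1]) * cell
    z = rng.uniform(0.0, 2000.0, size=n)
    return np.column_stack([x, y, z])
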