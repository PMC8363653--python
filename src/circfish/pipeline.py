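"""End-to-end orchestration: configuration, validation, reproducible runs.

A run is fully described by a :class:`RunConfig`; the same config and
seed reproduce byte-identical outputs.  Stage parameters default to the
study's stated constants (200 nm colocalization, 300 nm TLS-exon check,
six-RNA focus threshold, MSD lags 1-7, tracks longer than five frames,
0.01 um^2/s mobility threshold, 30-nt 3' trim, >25-nt length filter,
100-600 nt structure selection).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (classify_species, cytoplasmic_spliced_fraction,
                       detect_granules, exclude_spots_in_granules,
                       match_colocalized, per_cell_summary, segment_compartments)
from .detection import detect_and_fit, estimate_single_unit, spots_to_table
from .registration import AffineTransform, fit_affine
from .simulate import (SceneConfig, simulate_bead_field, simulate_smfish_scene)

logger = logging.getLogger("circfish")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "config_digest"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All stage parameters for a reproducible end-to-end run.

    With no input paths, a synthetic scene is generated from
    ``populations`` and the scene settings; ground truth is then part of
    the result bundle.
    """

    schema_version: int = CONFIG_SCHEMA_VERSION
    seed: int = 0
    out_dir: str | None = None
    # scene
    shape: tuple = (12, 192, 192)
    voxel_xy_nm: float = 100.0
    voxel_z_nm: float = 300.0
    sigma_xy_nm: float = 130.0
    sigma_z_nm: float = 300.0
    background: float = 100.0
    noise_sd: float = 2.0
    unit_amplitude: dict = field(default_factory=lambda: {"intron": 200.0, "exon": 200.0})
    populations: dict = field(default_factory=lambda: {
        "spliced_intron": {"nucleus": 4, "cytoplasm": 12},
        "pre_mRNA": {"nucleus": 4, "cytoplasm": 1},
        "mRNA": {"nucleus": 3, "cytoplasm": 8},
    })
    chromatic_shift_nm: tuple = (60.0, -40.0, 0.0)
    n_beads: int = 60
    bead_noise_nm: float = 5.0
    # detection
    detection_threshold_sd: float = 5.0
    # classification
    coloc_radius_nm: float = 200.0
    copy_threshold: float = 6.0
    # translation
    tls_radius_nm: float = 200.0
    tls_exon_radius_nm: float = 300.0
    # motion
    dt_s: float = 0.1
    max_lag: int = 7
    min_track_frames: int = 6
    free_D_threshold: float = 0.01
    # sequence
    trim_3ss_nt: int = 30
    min_intron_len_nt: int = 25
    structure_len_range: tuple = (100, 600)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(d["shape"])
        return d


def config_digest(config: RunConfig) -> str:
    """Stable SHA-256 digest of the scientific parameters (first 12 hex).

    The output location is excluded so identical analyses written to
    different directories share a digest.
    """
    d = config.to_dict()
    d.pop("out_dir", None)
    payload = json.dumps(d, sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Range and schema checks; returns a list of violations (empty = ok)."""
    v = []
    if config.schema_version != CONFIG_SCHEMA_VERSION:
        v.append(f"unsupported schema_version {config.schema_version}")
    if config.voxel_xy_nm <= 0 or config.voxel_z_nm <= 0:
        v.append("voxel sizes must be positive")
    if config.sigma_xy_nm <= 0 or config.sigma_z_nm <= 0:
        v.append("PSF widths must be positive")
    if config.coloc_radius_nm <= 0:
        v.append("colocalization radius must be positive")
    if config.tls_exon_radius_nm <= 0:
        v.append("TLS-exon radius must be positive")
    if config.copy_threshold < 1:
        v.append("focus copy threshold must be >= 1")
    if config.max_lag < 2:
        v.append("need at least 2 MSD lags")
    if config.min_track_frames < 2:
        v.append("minimum track length must be >= 2 frames")
    if config.dt_s <= 0:
        v.append("frame interval must be positive")
    if config.trim_3ss_nt < 0 or config.min_intron_len_nt < 0:
        v.append("sequence filters must be non-negative")
    lo, hi = config.structure_len_range
    if lo > hi or lo < 1:
        v.append("structure length range must satisfy 1 <= lo <= hi")
    for ch, amp in config.unit_amplitude.items():
        if amp <= 0:
            v.append(f"unit amplitude for {ch!r} must be positive")
    return v


def run_pipeline(config: RunConfig) -> dict:
    """Synthetic-scene end-to-end run: simulate, detect, register, classify.

    Stages run in dependency order; any stage failure raises with the
    stage name.  Returns a bundle with the ground truth, spot tables,
    the fitted chromatic transform, molecule records, granules, per-cell
    summary, and a provenance manifest.  When ``config.out_dir`` is set
    the tables are also written as CSV (each carrying the config digest)
    plus a ``manifest.json``.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    digest = config_digest(config)
    t0 = time.time()
    stage = "simulate"
    timings = {}
    try:
        scene_cfg = SceneConfig(
            shape=tuple(config.shape), voxel_xy_nm=config.voxel_xy_nm,
            voxel_z_nm=config.voxel_z_nm, sigma_xy_nm=config.sigma_xy_nm,
            sigma_z_nm=config.sigma_z_nm, background=config.background,
            noise_sd=config.noise_sd, unit_amplitude=dict(config.unit_amplitude),
            chromatic=AffineTransform(
                [[1, 0, 0], [0, 1, 0], [0, 0, 1]], list(config.chromatic_shift_nm)),
            seed=config.seed)
        images, truth = simulate_smfish_scene(scene_cfg, config.populations)
        ref, mov = simulate_bead_field(scene_cfg.chromatic, config.n_beads,
                                       noise_sd_nm=config.bead_noise_nm,
                                       seed=config.seed + 1)
        timings[stage] = time.time() - t0
        logger.info("simulated scene with %d molecules", len(truth.molecules))

        stage = "detect"
        t1 = time.time()
        spot_tables = {}
        for ch in ("intron", "exon"):
            spots = detect_and_fit(images[ch], config.voxel_xy_nm,
                                   config.voxel_z_nm, config.sigma_xy_nm,
                                   config.sigma_z_nm,
                                   threshold_sd=config.detection_threshold_sd,
                                   channel=ch)
            spot_tables[ch] = spots_to_table(spots)
        timings[stage] = time.time() - t1
        logger.info("detected %d intron / %d exon spots",
                    len(spot_tables["intron"]), len(spot_tables["exon"]))

        stage = "register"
        t1 = time.time()
        tform = fit_affine(ref, mov)   # maps intron frame -> exon frame
        corrected_exon = spot_tables["exon"].copy()
        if len(corrected_exon):
            pts = corrected_exon[["x_nm", "y_nm", "z_nm"]].to_numpy()
            corrected_exon[["x_nm", "y_nm", "z_nm"]] = tform.inverse().apply(pts)
        timings[stage] = time.time() - t1

        stage = "classify"
        t1 = time.time()
        mask = segment_compartments(images["dapi"], config.voxel_xy_nm)
        pairs = match_colocalized(spot_tables["intron"], corrected_exon,
                                  radius_nm=config.coloc_radius_nm)
        records, qc = classify_species(spot_tables["intron"], corrected_exon,
                                       pairs, mask)
        timings[stage] = time.time() - t1

        stage = "granules"
        t1 = time.time()
        units = {}
        for ch, tab in (("intron", spot_tables["intron"]), ("exon", corrected_exon)):
            try:
                units[ch] = estimate_single_unit(tab, channel=ch).unit
            except ValueError:
                units[ch] = None
        granules = pd.DataFrame()
        if all(u is not None for u in units.values()):
            granules = detect_granules(
                {c: images[c] for c in ("intron", "exon")}, units, scene_cfg,
                copy_threshold=config.copy_threshold, mask=mask)
            records = exclude_spots_in_granules(records, granules)
        timings[stage] = time.time() - t1

        stage = "summarize"
        summary = per_cell_summary(records, granules)
        spliced = cytoplasmic_spliced_fraction(records)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "schema_version": config.schema_version,
        "config_digest": digest,
        "seed": config.seed,
        "config": config.to_dict(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "counts": {"molecules_truth": len(truth.molecules),
                   "spots_intron": len(spot_tables["intron"]),
                   "spots_exon": len(spot_tables["exon"]),
                   "records": len(records), "granules": len(granules),
                   **qc},
    }
    bundle = {"images": images, "truth": truth, "spots": spot_tables,
              "transform": tform, "records": records, "granules": granules,
              "summary": summary, "cytoplasmic_spliced": spliced,
              "qc": qc, "manifest": manifest}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in (("spots_intron", spot_tables["intron"]),
                          ("spots_exon", spot_tables["exon"]),
                          ("molecules", records), ("granules", granules),
                          ("summary", summary)):
            tab = tab.copy()
            tab["config_digest"] = digest
            tab.to_csv(out / f"{name}.csv", index=False)
        tform.save(out / "chromatic_transform.json")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle
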