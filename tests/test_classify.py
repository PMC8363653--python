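"""Species classification, colocalization pairing, granules, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circfish.classify import (
    classify_species,
    cytoplasmic_spliced_fraction,
    detect_granules,
    exclude_spots_in_granules,
    granule_composition_slope,
    match_colocalized,
    per_cell_summary,
    rnase_r_retention,
    segment_compartments,
)
from circfish.simulate import (SceneConfig, simulate_granule_scene,
                               simulate_smfish_scene)
from circfish.simulate.scenes import gaussian_integral


def _spots(coords):
    return pd.DataFrame(coords, columns=["x_nm", "y_nm", "z_nm"])


def brute_force_mutual_nn(pa, pb, radius):
    """Independent exhaustive oracle: all-pairs distances, mutual argmin."""
    pairs = []
    for ia in range(len(pa)):
        for ib in range(len(pb)):
            d = float(np.linalg.norm(np.asarray(pa[ia]) - np.asarray(pb[ib])))
            if d > radius:
                continue
            nearest_b = min(range(len(pb)),
                            key=lambda j: np.linalg.norm(np.asarray(pa[ia]) - np.asarray(pb[j])))
            nearest_a = min(range(len(pa)),
                            key=lambda i: np.linalg.norm(np.asarray(pa[i]) - np.asarray(pb[ib])))
            if nearest_b == ib and nearest_a == ia:
                pairs.append((ia, ib))
    return sorted(set(pairs))


class TestMatchColocalized:
    def test_within_radius_paired(self):
        pairs = match_colocalized(_spots([[0, 0, 0]]), _spots([[0, 0, 150]]))
        assert len(pairs) == 1
        assert pairs.iloc[0]["distance_nm"] == pytest.approx(150.0)

    def test_beyond_radius_unpaired(self):
        pairs = match_colocalized(_spots([[0, 0, 0]]), _spots([[0, 0, 250]]))
        assert len(pairs) == 0

    def test_exactly_at_radius_paired(self):
        pairs = match_colocalized(_spots([[0, 0, 0]]), _spots([[0, 0, 200]]))
        assert len(pairs) == 1

    def test_mutual_nn_picks_nearer_of_two(self):
        # two intron spots at 150 and 180 nm from one exon spot: only the
        # nearer one pairs
        a = _spots([[150, 0, 0], [-180, 0, 0]])
        b = _spots([[0, 0, 0]])
        pairs = match_colocalized(a, b)
        assert len(pairs) == 1
        assert pairs.iloc[0]["index_a"] == 0

    def test_symmetry_roles_swap(self, rng):
        pa = rng.uniform(0, 2000, (8, 3))
        pb = rng.uniform(0, 2000, (6, 3))
        ab = match_colocalized(_spots(pa), _spots(pb), radius_nm=500)
        ba = match_colocalized(_spots(pb), _spots(pa), radius_nm=500)
        set_ab = {(r["index_a"], r["index_b"]) for _, r in ab.iterrows()}
        set_ba = {(r["index_b"], r["index_a"]) for _, r in ba.iterrows()}
        assert set_ab == set_ba

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 12), st.integers(0, 12))
    def test_matches_exhaustive_oracle(self, seed, na, nb):
        """Pairing equals brute-force mutual-NN search on <=12 spots."""
        r = np.random.default_rng(seed)
        pa = r.uniform(0, 1500, (na, 3))
        pb = r.uniform(0, 1500, (nb, 3))
        got = match_colocalized(_spots(pa), _spots(pb), radius_nm=300)
        got_set = sorted((int(x["index_a"]), int(x["index_b"]))
                         for _, x in got.iterrows())
        assert got_set == brute_force_mutual_nn(pa, pb, 300)


class TestClassifySpecies:
    def test_counts_by_definition(self, rng):
        # 10 paired + 5 intron-only + 3 exon-only
        base = rng.uniform(5000, 40000, (18, 3))
        intron = _spots(np.vstack([base[:10], base[10:15]]))
        exon = _spots(np.vstack([base[:10] + [0, 0, 50], base[15:]]))
        pairs = match_colocalized(intron, exon)
        records, qc = classify_species(intron, exon, pairs, mask=None)
        counts = records["species"].value_counts()
        assert counts["pre_mRNA"] == 10
        assert counts["spliced_intron"] == 5
        assert counts["mRNA"] == 3

    def test_conservation_invariant(self, rng):
        for trial in range(5):
            r = np.random.default_rng(trial)
            intron = _spots(r.uniform(0, 20000, (r.integers(0, 30), 3)))
            exon = _spots(r.uniform(0, 20000, (r.integers(0, 30), 3)))
            pairs = match_colocalized(intron, exon)
            records, _ = classify_species(intron, exon, pairs, mask=None)
            assert len(records) == len(intron) + len(exon) - len(pairs)

    def test_premrna_partner_distance_recorded(self):
        intron = _spots([[0, 0, 0]])
        exon = _spots([[120, 0, 0]])
        pairs = match_colocalized(intron, exon)
        records, _ = classify_species(intron, exon, pairs, mask=None)
        assert records.iloc[0]["partner_distance_nm"] == pytest.approx(120.0)
        only = classify_species(intron, _spots(np.empty((0, 3))),
                                match_colocalized(intron, _spots(np.empty((0, 3)))),
                                mask=None)[0]
        assert np.isnan(only.iloc[0]["partner_distance_nm"])

    def test_scene_round_trip_98pct_spliced(self):
        """A scene generated with 98% partner-free cytoplasmic introns is
        reported as ~98% spliced (binomial tolerance)."""
        cfg = SceneConfig(shape=(12, 400, 400), noise_sd=0.0, seed=21)
        images, truth = simulate_smfish_scene(
            cfg, {"spliced_intron": {"cytoplasm": 98},
                  "pre_mRNA": {"cytoplasm": 2}})
        intron = truth.molecules.query("species != 'mRNA'")[["x_nm", "y_nm", "z_nm"]]
        exon = truth.molecules.query("species != 'spliced_intron'")[["x_nm", "y_nm", "z_nm"]]
        pairs = match_colocalized(intron.reset_index(drop=True),
                                  exon.reset_index(drop=True))
        records, _ = classify_species(intron.reset_index(drop=True),
                                      exon.reset_index(drop=True), pairs, mask=None)
        frac = cytoplasmic_spliced_fraction(records)
        assert frac["fraction_spliced"] == pytest.approx(0.98, abs=0.001)


class TestSegmentation:
    def test_three_nuclei_recovered(self):
        from circfish.simulate.scenes import CellGeometry
        cells = [CellGeometry((2500, 2500, 1500), (1500, 1500, 1400), (2400, 2400, 1500)),
                 (CellGeometry((7000, 2500, 1500), (1200, 1200, 1400), (2200, 2200, 1500))),
                 (CellGeometry((4800, 7000, 1500), (1400, 1400, 1400), (2300, 2300, 1500)))]
        cfg = SceneConfig(shape=(10, 96, 96), cells=cells, noise_sd=2.0, seed=2)
        images, _ = simulate_smfish_scene(cfg, {})
        mask = segment_compartments(images["dapi"], cfg.voxel_xy_nm)
        assert mask.nucleus_labels.max() == 3
        # each true nucleus center maps to a distinct label, in-nucleus
        labels = set()
        for c in cells:
            cell, comp = mask.lookup(c.center_nm[0], c.center_nm[1])
            assert comp == "nucleus"
            labels.add(cell)
        assert len(labels) == 3

    def test_nucleus_mask_iou_against_truth(self):
        from circfish.simulate.scenes import CellGeometry
        cell = CellGeometry((4800, 4800, 1500), (2000, 2000, 1400), (4000, 4000, 1500))
        cfg = SceneConfig(shape=(10, 96, 96), cells=[cell], noise_sd=2.0, seed=3)
        images, _ = simulate_smfish_scene(cfg, {})
        mask = segment_compartments(images["dapi"], cfg.voxel_xy_nm)
        yy, xx = np.meshgrid(np.arange(96) * 100.0, np.arange(96) * 100.0,
                             indexing="ij")
        true2d = ((xx - 4800) / 2000) ** 2 + ((yy - 4800) / 2000) ** 2 <= 1.0
        got = mask.nucleus_labels > 0
        iou = (true2d & got).sum() / (true2d | got).sum()
        assert iou >= 0.9

    def test_blank_image_fails(self):
        with pytest.raises(ValueError):
            segment_compartments(np.zeros((8, 64, 64)), 100.0)


class TestGranules:
    @pytest.fixture
    def unit(self, small_config):
        return gaussian_integral(small_config.unit_amplitude["intron"],
                                 small_config.sigma_xy_nm,
                                 small_config.sigma_z_nm)

    def test_copies_recovered_noise_free(self, small_config, unit):
        images, _ = simulate_granule_scene(small_config, [(12, 6)])
        g = detect_granules(images, {"intron": unit, "exon": unit}, small_config)
        assert len(g) == 1
        assert g.iloc[0]["intron_copies"] == pytest.approx(12.0, rel=0.02)
        assert g.iloc[0]["exon_copies"] == pytest.approx(6.0, rel=0.02)
        assert g.iloc[0]["type"] == "colocalized"

    def test_six_copy_admission_boundary(self, small_config, unit):
        """(6,6) passes the six-RNA rule; (5,5) does not."""
        images, _ = simulate_granule_scene(small_config, [(6, 6), (5, 5)])
        g = detect_granules(images, {"intron": unit, "exon": unit}, small_config)
        assert len(g) == 1
        assert g.iloc[0]["intron_copies"] == pytest.approx(6.0, rel=0.02)

    def test_intron_only_granule_admitted(self, small_config, unit):
        images, _ = simulate_granule_scene(small_config, [(9, 0)])
        g = detect_granules(images, {"intron": unit, "exon": unit}, small_config)
        assert len(g) == 1
        assert g.iloc[0]["type"] == "intron_only"
        assert g.iloc[0]["exon_copies"] == pytest.approx(0.0, abs=0.5)

    def test_missing_unit_fails(self, small_config, unit):
        images, _ = simulate_granule_scene(small_config, [(8, 8)])
        with pytest.raises(ValueError):
            detect_granules(images, {"intron": unit}, small_config)

    def test_spots_inside_granules_absorbed(self):
        granules = pd.DataFrame([{"x_nm": 1000.0, "y_nm": 1000.0, "z_nm": 1500.0,
                                  "radius_nm": 600.0}])
        spots = _spots([[1100, 1000, 1500], [5000, 5000, 1500]])
        kept = exclude_spots_in_granules(spots, granules)
        assert len(kept) == 1
        assert kept.iloc[0]["x_nm"] == 5000


class TestCompositionSlope:
    def test_exact_two_to_one(self):
        g = pd.DataFrame({"exon_copies": [2.0, 4, 6, 8],
                          "intron_copies": [4.0, 8, 12, 16],
                          "type": "colocalized"})
        fit = granule_composition_slope(g)
        assert fit["slope"] == pytest.approx(2.0, abs=1e-9)
        assert fit["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_control_cells_slope_one(self):
        g = pd.DataFrame({"exon_copies": [3.0, 5, 9], "intron_copies": [3.0, 5, 9],
                          "type": "colocalized"})
        assert granule_composition_slope(g)["slope"] == pytest.approx(1.0)

    def test_generator_round_trip_slope_two(self, unit_integral):
        """100 rendered granules at intron=2x exon, 10% brightness noise:
        fitted slope 2.0 +/- 0.1."""
        r = np.random.default_rng(7)
        exon = r.integers(3, 11, size=100)
        cfg = SceneConfig(shape=(16, 256, 256), noise_sd=5.0, seed=7)
        images, _ = simulate_granule_scene(cfg, [(int(2 * e), int(e)) for e in exon],
                                           intensity_cv=0.10)
        g = detect_granules(images, {"intron": unit_integral, "exon": unit_integral}, cfg)
        fit = granule_composition_slope(g)
        assert fit["slope"] == pytest.approx(2.0, abs=0.1)

    def test_slope_consistency_on_truth_counts(self):
        """Estimator consistency: OLS on 1000 ground-truth granules with
        correlated brightness jitter converges to the generative ratio."""
        r = np.random.default_rng(42)
        exon = r.uniform(2, 12, 1000)
        gain = r.normal(1.0, 0.1, 1000)
        g = pd.DataFrame({"exon_copies": exon * gain,
                          "intron_copies": 2 * exon * gain,
                          "type": "colocalized"})
        assert granule_composition_slope(g)["slope"] == pytest.approx(2.0, rel=0.02)

    def test_degenerate_inputs_fail(self):
        g = pd.DataFrame({"exon_copies": [5.0, 5, 5], "intron_copies": [1.0, 2, 3],
                          "type": "colocalized"})
        with pytest.raises(ValueError):
            granule_composition_slope(g)
        with pytest.raises(ValueError):
            granule_composition_slope(g.iloc[:2])


class TestSummaries:
    def test_single_cell_counts(self):
        records = pd.DataFrame({
            "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0,
            "species": ["spliced_intron"] * 5,
            "compartment": ["cytoplasm"] * 5,
            "cell": [1] * 5, "partner_distance_nm": np.nan})
        summary = per_cell_summary(records)
        row = summary.query("cell == 1 and compartment == 'cytoplasm' "
                            "and species == 'spliced_intron'")
        assert row["count"].iloc[0] == 5

    def test_empty_records_empty_table(self):
        summary = per_cell_summary(pd.DataFrame(
            columns=["x_nm", "y_nm", "z_nm", "species", "compartment",
                     "cell", "partner_distance_nm"]))
        assert len(summary) == 0

    def test_multi_cell_counts_match_ground_truth(self, rng):
        rows = []
        expected = {}
        for cell in (1, 2, 3):
            for comp in ("nucleus", "cytoplasm"):
                for sp in ("mRNA", "spliced_intron", "pre_mRNA"):
                    n = int(rng.integers(0, 6))
                    expected[(cell, comp, sp)] = n
                    for _ in range(n):
                        rows.append({"x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0,
                                     "species": sp, "compartment": comp,
                                     "cell": cell, "partner_distance_nm": np.nan})
        summary = per_cell_summary(pd.DataFrame(rows))
        for (cell, comp, sp), n in expected.items():
            got = summary.query("cell == @cell and compartment == @comp "
                                "and species == @sp")["count"]
            assert (got.iloc[0] if len(got) else 0) == n


class TestRnaseRRetention:
    @staticmethod
    def _table(cells, counts):
        rows = []
        for cell in range(cells):
            for (comp, sp), n in counts.items():
                rows.append({"cell": cell, "compartment": comp, "species": sp,
                             "count": n})
        return pd.DataFrame(rows)

    def test_identical_tables_full_retention(self):
        t = self._table(10, {("cytoplasm", "spliced_intron"): 4,
                             ("nucleus", "mRNA"): 7})
        res = rnase_r_retention(t, t, n_boot=200)
        assert np.allclose(res["retained"], 1.0)

    def test_circularity_signature(self):
        """Cytoplasmic introns persist (1.0) while mRNAs vanish (0.0)."""
        control = self._table(8, {("cytoplasm", "spliced_intron"): 5,
                                  ("cytoplasm", "mRNA"): 6,
                                  ("nucleus", "mRNA"): 9})
        treated = self._table(8, {("cytoplasm", "spliced_intron"): 5,
                                  ("cytoplasm", "mRNA"): 0,
                                  ("nucleus", "mRNA"): 0})
        res = rnase_r_retention(control, treated, n_boot=200).set_index(
            ["compartment", "species"])
        assert res.loc[("cytoplasm", "spliced_intron"), "retained"] == pytest.approx(1.0)
        assert res.loc[("cytoplasm", "mRNA"), "retained"] == pytest.approx(0.0)
        assert res.loc[("nucleus", "mRNA"), "retained"] == pytest.approx(0.0)

    def test_zero_control_reported_missing(self):
        control = self._table(5, {("cytoplasm", "mRNA"): 0})
        treated = self._table(5, {("cytoplasm", "mRNA"): 3})
        res = rnase_r_retention(control, treated, n_boot=50)
        assert np.isnan(res["retained"].iloc[0])

    def test_bootstrap_recovers_poisson_retention(self, rng):
        """Poisson-resampled tables at true retention 0.8: estimate and CI
        cover the truth."""
        lam = 20.0
        rows_c = [{"cell": i, "compartment": "cytoplasm",
                   "species": "spliced_intron", "count": rng.poisson(lam)}
                  for i in range(60)]
        rows_t = [{"cell": i, "compartment": "cytoplasm",
                   "species": "spliced_intron", "count": rng.poisson(0.8 * lam)}
                  for i in range(60)]
        res = rnase_r_retention(pd.DataFrame(rows_c), pd.DataFrame(rows_t),
                                n_boot=2000, seed=1)
        row = res.iloc[0]
        assert row["retained"] == pytest.approx(0.8, abs=0.08)
        assert row["ci_low"] < 0.8 < row["ci_high"]
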