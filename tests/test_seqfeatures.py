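"""Branch-site calling and G-content rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circfish.seqfeatures import (
    call_branch_site,
    filter_junction_reads,
    free_energy_density,
    g_content,
    positional_g_profile,
    prepare_intron_set,
    structure_filter,
)
from circfish.simulate import random_sequence, simulate_junction_reads


def _intron(length, branch_pos, seed=0, g_bias=0.3):
    rng = np.random.default_rng(seed)
    return random_sequence(length, g_bias, rng, force={branch_pos: "A"})


def oracle_branch_support(reads, intron, window, min_overhang, budget_frac=0.1):
    """All-rotations exhaustive oracle, independent of the caller.

    For every candidate A in the window, slide each read over the doubled
    circle; a read supports the candidate with its minimal Hamming
    distance among junction-covering placements.
    """
    L = len(intron)
    candidates = [p for p in range(L - window + 1, L + 1) if intron[p - 1] == "A"]
    support = {p: 0 for p in candidates}
    n_assigned = 0
    for read in reads:
        rl = len(read)
        budget = max(2, int(round(budget_frac * rl)))
        best = {}
        for p in candidates:
            circle = intron[:p]
            doubled = circle + circle
            best_mm = None
            for s in range(len(circle)):
                left = len(circle) - s  # nt before the junction inside the read
                if left < min_overhang or rl - left < min_overhang:
                    continue
                window_seq = doubled[s:s + rl]
                if len(window_seq) < rl:
                    continue
                mm = sum(1 for a, b in zip(read, window_seq) if a != b)
                if best_mm is None or mm < best_mm:
                    best_mm = mm
            if best_mm is not None and best_mm <= budget:
                best[p] = best_mm
        if not best:
            continue
        m = min(best.values())
        winners = [p for p, v in best.items() if v == m]
        if len(winners) == 1:
            support[winners[0]] += 1
            n_assigned += 1
    return support, n_assigned


class TestFilterJunctionReads:
    def test_read_ending_at_junction_removed(self):
        reads = pd.DataFrame({"start": [0], "end": [50]})
        assert len(filter_junction_reads(reads, junction_index=50)) == 0

    def test_overhang_arithmetic(self):
        # junction at 50; read [30, 70): 20 nt each side, overhang 10 -> kept
        reads = pd.DataFrame({"start": [30, 45, 0], "end": [70, 95, 55]})
        kept = filter_junction_reads(reads, junction_index=50, min_overhang=10)
        assert kept["start"].tolist() == [30]

    def test_empty_set(self):
        reads = pd.DataFrame(columns=["start", "end"])
        assert len(filter_junction_reads(reads, 50)) == 0


class TestCallBranchSite:
    def test_error_free_round_trip_distance_40(self):
        """600-nt intron, branch A at length-40: dominant call at distance
        40 with support fraction 1.0."""
        intron = _intron(600, 560, seed=1)
        reads = simulate_junction_reads(intron, 560, 300, 200, seed=1)
        calls = call_branch_site(reads, intron)
        top = calls.iloc[0]
        assert top["branch_pos"] == 560
        assert top["distance_to_3ss"] == 40
        assert top["branch_base"] == "A"
        assert top["fraction"] == 1.0

    def test_one_percent_error_keeps_dominant_support(self):
        intron = _intron(600, 560, seed=2)
        reads = simulate_junction_reads(intron, 560, 300, 300,
                                        error_rate=0.01, seed=2)
        calls = call_branch_site(reads, intron)
        assert calls.iloc[0]["distance_to_3ss"] == 40
        assert calls.iloc[0]["fraction"] >= 0.95

    def test_linear_reads_give_no_support(self):
        intron = _intron(400, 360, seed=3)
        # windows of the linear intron that never cross any junction
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 200, 50)
        reads = [intron[s:s + 100] for s in starts]
        calls = call_branch_site(reads, intron)
        assert len(calls) == 0

    def test_two_branch_sites_mixture_fractions(self):
        """70/30 usage of two branch A's recovers both fractions."""
        intron = _intron(500, 460, seed=4)
        intron = intron[:419] + "A" + intron[420:]   # second branch at 420
        r1 = simulate_junction_reads(intron, 460, 150, 140, seed=5)
        r2 = simulate_junction_reads(intron, 420, 150, 60, seed=6)
        reads = pd.concat([r1, r2], ignore_index=True)
        calls = call_branch_site(reads, intron).set_index("branch_pos")
        sd = np.sqrt(0.7 * 0.3 / 200)
        assert calls.loc[460, "fraction"] == pytest.approx(0.7, abs=3 * sd)
        assert calls.loc[420, "fraction"] == pytest.approx(0.3, abs=3 * sd)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_rotations_oracle(self, seed):
        """Caller support equals the exhaustive rotation oracle on small
        instances (intron <= 200 nt, <= 50 reads)."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(120, 201))
        bp = int(rng.integers(L - 80, L))
        intron = random_sequence(L, 0.3, rng, force={bp: "A"})
        reads = simulate_junction_reads(intron, bp, 40, 30,
                                        error_rate=0.02, seed=seed,
                                        junction_fraction=0.8)
        calls = call_branch_site(reads["sequence"].tolist(), intron,
                                 window=100, min_overhang=10)
        support, n_assigned = oracle_branch_support(
            reads["sequence"].tolist(), intron, 100, 10)
        got = {int(r["branch_pos"]): int(r["supporting_reads"])
               for _, r in calls.iterrows()}
        expected = {p: s for p, s in support.items() if s > 0}
        assert got == expected
        if calls.shape[0]:
            assert int(calls.iloc[0]["total_junction_reads"]) == n_assigned

    def test_empty_reads(self):
        assert len(call_branch_site([], _intron(200, 180))) == 0


class TestGContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGGG", 1.0),
        ("GGGGCC", 4 / 6),
        ("ATTCT", 0.0),
        ("GNGN", 0.5),   # N counts in the denominator only
    ])
    def test_known_fractions(self, seq, expected):
        assert g_content(seq) == pytest.approx(expected)

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            g_content("")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    def test_agrees_with_direct_counting(self, seq):
        direct = sum(1 for c in seq if c == "G") / len(seq)
        assert g_content(seq) == pytest.approx(direct)


class TestPrepareIntronSet:
    def test_genomewide_trim_and_filter(self):
        introns = pd.DataFrame({"id": ["a", "b", "c"],
                                "sequence": ["A" * 100, "A" * 55, "A" * 56]})
        out = prepare_intron_set(introns, mode="genomewide")
        # 100 -> 70 kept; 55 -> 25 removed (not > 25); 56 -> 26 kept
        assert out["id"].tolist() == ["a", "c"]
        assert out["sequence"].str.len().tolist() == [70, 26]

    def test_circular_mode_unchanged(self):
        introns = pd.DataFrame({"id": ["a"], "sequence": ["ACGT" * 10]})
        out = prepare_intron_set(introns, mode="circular")
        assert out.iloc[0]["sequence"] == "ACGT" * 10

    def test_short_sequences_dropped_entirely(self):
        introns = pd.DataFrame({"id": ["a"], "sequence": ["A" * 20]})
        assert len(prepare_intron_set(introns, mode="genomewide")) == 0


class TestPositionalGProfile:
    def test_hand_counted_5p(self):
        prof = positional_g_profile(["GA", "GG"], anchor="5p")
        assert prof["g_fraction"].tolist() == [1.0, 0.5]

    def test_hand_counted_3p(self):
        prof = positional_g_profile(["GA", "GG"], anchor="3p")
        assert prof["g_fraction"].tolist() == [0.5, 1.0]

    def test_binomial_flat_profile(self):
        from circfish.simulate import simulate_intron_set
        introns = simulate_intron_set(1000, 80, g_bias=0.4, seed=9)
        prof = positional_g_profile(introns, anchor="5p")
        assert np.all(np.abs(prof["g_fraction"] - 0.4) < 0.05)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=30),
                    min_size=1, max_size=20))
    def test_denominator_monotone_and_matches_counting(self, seqs):
        for anchor in ("5p", "3p"):
            prof = positional_g_profile(seqs, anchor=anchor)
            n = prof["n_sequences"].to_numpy()
            assert np.all(np.diff(n) <= 0)
            for _, row in prof.iterrows():
                i = int(row["position"]) - 1
                elig = [s for s in seqs if len(s) > i]
                g = sum(1 for s in elig
                        if (s[i] if anchor == "5p" else s[-1 - i]) == "G")
                assert row["g_fraction"] == pytest.approx(g / len(elig))


class TestStructureFilter:
    @pytest.mark.parametrize("length,kept,out_len", [
        (99, False, None), (100, True, 70), (600, True, 570), (601, False, None)])
    def test_length_window_and_trim(self, length, kept, out_len):
        introns = pd.DataFrame({"id": ["x"], "sequence": ["A" * length]})
        out = structure_filter(introns)
        assert (len(out) == 1) is kept
        if kept:
            assert len(out.iloc[0]["sequence"]) == out_len


class TestFreeEnergyDensity:
    def test_arithmetic(self):
        assert free_energy_density(570, -57.0) == pytest.approx(0.1)

    def test_zero_dg(self):
        assert free_energy_density(100, 0.0) == 0.0

    def test_zero_length_fails(self):
        with pytest.raises(ValueError):
            free_energy_density(0, -10.0)
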