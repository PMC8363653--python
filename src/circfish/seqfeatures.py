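"""Circular-junction branch-site calling and intron G-content profiles.

A stable intron lariat that escapes debranching is a covalent circle
joining the intron 5' end to the branch-point adenosine near the 3'
splice site.  Reads across that junction therefore contain intron
sequence ending at the branch base followed immediately by the intron 5'
end.  The caller scores every candidate branch position in a window
before the 3' splice site by counting junction-spanning reads that match
the implied circular reference, and reports candidates ranked by support.

The G-content utilities reproduce the composition analysis used to ask
whether exported circular introns are unusually G-rich: full-length G
fraction for circular introns, a 30-nt 3' trim (the average branch to
3'ss distance) plus a >25-nt length filter for the genome-wide
background, and 5'/3'-anchored per-position G profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "JunctionCall",
    "filter_junction_reads",
    "call_branch_site",
    "g_content",
    "prepare_intron_set",
    "positional_g_profile",
    "structure_filter",
    "free_energy_density",
]

DEFAULT_BRANCH_WINDOW_NT = 100
DEFAULT_MIN_OVERHANG_NT = 10
TRIM_3SS_NT = 30          # average branch-site to 3'ss distance
MIN_INTRON_LEN_NT = 25    # "longer than 25 nt" after trimming
STRUCTURE_LEN_RANGE = (100, 600)


@dataclass
class JunctionCall:
    """One called branch site (1-based intron coordinate)."""

    branch_pos: int
    branch_base: str
    distance_to_3ss: int
    supporting_reads: int
    total_junction_reads: int

    @property
    def fraction(self) -> float:
        return (self.supporting_reads / self.total_junction_reads
                if self.total_junction_reads else 0.0)


def filter_junction_reads(alignments: pd.DataFrame,
                          junction_index: int,
                          min_overhang: int = DEFAULT_MIN_OVERHANG_NT) -> pd.DataFrame:
    """Keep reads that truly span a junction.

    ``alignments`` carries ``start, end`` (0-based, end-exclusive)
    coordinates of each read on a junction reference in which the
    junction sits between index ``junction_index - 1`` and
    ``junction_index``.  A read is kept iff it covers at least
    ``min_overhang`` nt on each side; reads ending exactly at the
    junction have zero overhang and are removed.
    """
    if len(alignments) == 0:
        return alignments
    keep = ((alignments["start"] <= junction_index - min_overhang)
            & (alignments["end"] >= junction_index + min_overhang))
    return alignments[keep].reset_index(drop=True)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def call_branch_site(reads,
                     intron_seq: str,
                     window: int = DEFAULT_BRANCH_WINDOW_NT,
                     min_overhang: int = DEFAULT_MIN_OVERHANG_NT,
                     max_mismatches: int | None = None,
                     a_only: bool = True) -> pd.DataFrame:
    """Rank candidate branch sites by junction-spanning read support.

    For every candidate position ``p`` in the last ``window`` nt of the
    intron (adenosines only, unless ``a_only=False``), the implied
    circular junction reference is ``intron[:p]`` joined end-to-start.
    Each read is aligned at every offset that keeps the junction covered
    with >= ``min_overhang`` nt on both sides, and is assigned to the
    candidate with the fewest mismatches, provided that count is within
    the mismatch budget (default: 10% of the read length) and the best
    candidate is unique.  ``N`` bases never match.

    ``reads`` may be a DataFrame with a ``sequence`` column or a list of
    strings.  Returns candidates with >= 1 supporting read, sorted by
    support (the dominant call first), with columns ``branch_pos,
    branch_base, distance_to_3ss, supporting_reads,
    total_junction_reads, fraction``.  Distance to the 3' splice site
    counts nucleotides after the branch base: ``len(intron) - p``.
    """
    intron_seq = intron_seq.upper()
    L = len(intron_seq)
    if window < 1 or window > L:
        raise ValueError("candidate window must lie within the intron")
    seqs = (list(reads["sequence"]) if isinstance(reads, pd.DataFrame)
            else [str(r) for r in reads])
    cols = ["branch_pos", "branch_base", "distance_to_3ss",
            "supporting_reads", "total_junction_reads", "fraction"]
    if not seqs:
        return pd.DataFrame(columns=cols)

    candidates = [p for p in range(L - window + 1, L + 1)
                  if (not a_only) or intron_seq[p - 1] == "A"]
    if not candidates:
        return pd.DataFrame(columns=cols)

    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)

    n_reads = len(seqs)
    best_mm = np.full((len(candidates), n_reads), np.iinfo(np.int32).max,
                      dtype=np.int32)
    intron_arr = _encode(intron_seq)
    n_code = ord("N")
    for rl, read_idx in by_len.items():
        if rl < 2 * min_overhang:
            continue
        budget = (max_mismatches if max_mismatches is not None
                  else max(2, int(round(0.1 * rl))))
        reads_arr = np.stack([_encode(seqs[i]) for i in read_idx])
        # N in a read matches nothing
        for ci, p in enumerate(candidates):
            left_len = min(rl - min_overhang, p)
            if left_len < min_overhang:
                continue
            # right flank tiles the circle in case the read wraps past it
            jref = np.concatenate([intron_arr[p - left_len:p],
                                   np.resize(intron_arr[:p], rl)])
            jref = np.where(jref == n_code, 0, jref)  # reference N never matches
            jlen = left_len
            windows = np.lib.stride_tricks.sliding_window_view(jref, rl)
            o_lo = max(0, jlen + min_overhang - rl)
            o_hi = min(len(windows) - 1, jlen - min_overhang)
            if o_hi < o_lo:
                continue
            mm = (windows[o_lo:o_hi + 1][None, :, :]
                  != reads_arr[:, None, :]).sum(axis=2)
            best = mm.min(axis=1)
            best = np.where(best <= budget, best, np.iinfo(np.int32).max)
            best_mm[ci, np.array(read_idx)] = np.minimum(
                best_mm[ci, np.array(read_idx)], best.astype(np.int32))

    sentinel = np.iinfo(np.int32).max
    read_best = best_mm.min(axis=0)
    assigned = read_best < sentinel
    support = np.zeros(len(candidates), dtype=int)
    n_assigned = 0
    for ri in np.nonzero(assigned)[0]:
        winners = np.nonzero(best_mm[:, ri] == read_best[ri])[0]
        if len(winners) == 1:
            support[winners[0]] += 1
            n_assigned += 1
    rows = []
    for ci, p in enumerate(candidates):
        if support[ci] == 0:
            continue
        rows.append({"branch_pos": p, "branch_base": intron_seq[p - 1],
                     "distance_to_3ss": L - p,
                     "supporting_reads": int(support[ci]),
                     "total_junction_reads": int(n_assigned),
                     "fraction": support[ci] / n_assigned})
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("supporting_reads", ascending=False,
                           kind="stable").reset_index(drop=True)


def g_content(sequence: str) -> float:
    """G fraction over the full sequence length; N counts in the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return s.count("G") / len(s)


def prepare_intron_set(introns: pd.DataFrame,
                       mode: str = "genomewide",
                       trim_nt: int = TRIM_3SS_NT,
                       min_len_nt: int = MIN_INTRON_LEN_NT) -> pd.DataFrame:
    """Apply the composition-analysis selection rules.

    ``genomewide``: remove the last ``trim_nt`` nucleotides from the 3'
    splice site (the average branch-to-3'ss distance, so the branch-distal
    tail common to all introns does not dominate) and keep only sequences
    longer than ``min_len_nt`` after trimming.  ``circular``: full-length
    sequences, unchanged.
    """
    if mode == "circular":
        return introns.reset_index(drop=True)
    if mode != "genomewide":
        raise ValueError("mode must be 'genomewide' or 'circular'")
    out = introns.copy()
    out["sequence"] = out["sequence"].str[:-trim_nt].where(
        out["sequence"].str.len() > trim_nt, "")
    out = out[out["sequence"].str.len() > min_len_nt]
    return out.reset_index(drop=True)


def positional_g_profile(introns: pd.DataFrame | list,
                         anchor: str = "5p") -> pd.DataFrame:
    """Per-position G fraction with sequences aligned at one splice site.

    ``anchor='5p'`` indexes positions from the 5' splice site inward;
    ``anchor='3p'`` walks 5'-ward from the 3' end (position 1 = last
    base).  At position i the fraction is (# introns with G at i) /
    (# introns of length >= i), so the denominator is non-increasing
    with distance from the anchor on ragged-length sets.

    Returns columns ``position, g_fraction, n_sequences``.
    """
    seqs = (list(introns["sequence"]) if isinstance(introns, pd.DataFrame)
            else [str(s) for s in introns])
    if anchor not in ("5p", "3p"):
        raise ValueError("anchor must be '5p' or '3p'")
    if not seqs:
        return pd.DataFrame(columns=["position", "g_fraction", "n_sequences"])
    max_len = max(len(s) for s in seqs)
    g_count = np.zeros(max_len, dtype=int)
    n_count = np.zeros(max_len, dtype=int)
    for s in seqs:
        s = s.upper()
        if anchor == "3p":
            s = s[::-1]
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        n_count[:len(arr)] += 1
        g_count[:len(arr)] += (arr == ord("G"))
    return pd.DataFrame({"position": np.arange(1, max_len + 1),
                         "g_fraction": g_count / n_count,
                         "n_sequences": n_count})


def structure_filter(introns: pd.DataFrame,
                     length_range: tuple[int, int] = STRUCTURE_LEN_RANGE,
                     trim_nt: int = TRIM_3SS_NT) -> pd.DataFrame:
    """Select 100-600 nt introns and trim the 30-nt branch-distal tail.

    This prepares sequences for an external secondary-structure
    predictor; the folding itself is not performed here (see
    :func:`free_energy_density` for ingesting its output).
    """
    lo, hi = length_range
    out = introns[introns["sequence"].str.len().between(lo, hi)].copy()
    out["sequence"] = out["sequence"].str[:-trim_nt]
    return out.reset_index(drop=True)


def free_energy_density(length_nt: int, delta_g: float) -> float:
    """Minimum-free-energy density -dG/nt from an external predictor's dG."""
    if length_nt <= 0:
        raise ValueError("sequence length must be positive")
    return -delta_g / length_nt
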