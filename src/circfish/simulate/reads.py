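"""Synthetic sequences: circular-junction reads and random intron sets.

A circular intron produced by failed lariat debranching joins its 5' end
to the branch-point adenosine, so sequencing reads across that junction
contain the 3'-proximal branch flank followed immediately by the intron
5' end.  The generator builds such reads by windowing the circularized
intron string (the lariat tail downstream of the branch is absent, as it
is removed by 3'->5' exonuclease treatment).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["simulate_junction_reads", "simulate_intron_set", "random_sequence"]

_BASES = np.array(list("ACGT"))


def random_sequence(length: int, g_bias: float, rng: np.random.Generator,
                    force: dict[int, str] | None = None) -> str:
    """Random DNA with P(G) = g_bias and the rest uniform over A/C/T.

    ``force`` optionally pins 1-based positions to given bases (e.g. a
    branch-point adenosine).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= g_bias <= 1.0:
        raise ValueError("g_bias must be in [0, 1]")
    other = (1.0 - g_bias) / 3.0
    probs = {"A": other, "C": other, "G": g_bias, "T": other}
    seq = rng.choice(_BASES, size=length, p=[probs[b] for b in "ACGT"])
    if force:
        for pos, base in force.items():
            if not 1 <= pos <= length:
                raise ValueError(f"forced position {pos} outside sequence")
            seq[pos - 1] = base
    return "".join(seq)


def simulate_junction_reads(intron_seq: str,
                            branch_pos: int,
                            read_len: int,
                            n_reads: int,
                            error_rate: float = 0.0,
                            seed: int = 0,
                            junction_fraction: float = 1.0,
                            min_overhang: int = 10) -> pd.DataFrame:
    """Reads over the circular 5'ss-branch-site junction.

    The circle is ``intron_seq[:branch_pos]`` (1-based inclusive branch
    position); the junction sits between the branch base and intron
    position 1.  A fraction ``junction_fraction`` of reads is drawn with
    at least ``min_overhang`` nt on each side of the junction; the rest
    are linear windows of the circle that never cross it.  Substitution
    errors are applied per base at ``error_rate``.

    Returns a DataFrame with columns ``name, sequence, covers_junction``
    (ground truth), writable as FASTQ via :func:`circfish.io.write_fastq`.
    """
    intron_seq = intron_seq.upper()
    L = len(intron_seq)
    if not 1 <= branch_pos <= L:
        raise ValueError("branch_pos must be within the intron")
    if read_len < 2 * min_overhang:
        raise ValueError("read_len must be >= 2 * min_overhang")
    if intron_seq[branch_pos - 1] != "A":
        warnings.warn("branch base is not adenosine; branch points are canonically 'A'",
                      stacklevel=2)
    circle = intron_seq[:branch_pos]
    C = len(circle)
    if C < read_len:
        raise ValueError("circle shorter than read length is not supported")
    rng = np.random.default_rng(seed)

    lo = C - read_len + min_overhang
    hi = C - min_overhang
    if lo > hi:
        raise ValueError("no start position satisfies the overhang constraint")
    doubled = circle + circle
    rows = []
    for i in range(n_reads):
        covers = rng.uniform() < junction_fraction
        if covers:
            s = int(rng.integers(lo, hi + 1))
        else:
            if C == read_len:
                s = 0
            else:
                s = int(rng.integers(0, C - read_len + 1))
        seq = doubled[s:s + read_len]
        if error_rate > 0:
            seq = _mutate(seq, error_rate, rng)
        rows.append({"name": f"read_{i}", "sequence": seq,
                     "covers_junction": bool(covers and s != 0)})
    return pd.DataFrame(rows, columns=["name", "sequence", "covers_junction"])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.uniform(size=len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_intron_set(n: int,
                        length,
                        g_bias=0.25,
                        seed: int = 0,
                        prefix: str = "intron") -> pd.DataFrame:
    """Random intron sequences with controlled G composition.

    ``length`` may be an int (fixed), a (lo, hi) tuple (uniform integer
    lengths), or a sequence of per-intron lengths.  ``g_bias`` likewise
    may be scalar or per-intron.  Base composition matches the bias in
    expectation.

    Returns a DataFrame with columns ``id, sequence``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(length, int):
        lengths = np.full(n, length)
    elif isinstance(length, tuple) and len(length) == 2:
        lengths = rng.integers(length[0], length[1] + 1, size=n)
    else:
        lengths = np.asarray(length)
        if len(lengths) != n:
            raise ValueError("per-intron lengths must have length n")
    biases = np.full(n, g_bias, dtype=float) if np.isscalar(g_bias) else np.asarray(g_bias, dtype=float)
    rows = [{"id": f"{prefix}_{i}",
             "sequence": random_sequence(int(lengths[i]), float(biases[i]), rng)}
            for i in range(n)]
    return pd.DataFrame(rows, columns=["id", "sequence"])
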