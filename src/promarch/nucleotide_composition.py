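"""Per-position base composition and initiator dinucleotide profiling.

Sequences are TSS-anchored windows in transcript orientation (positions
-upstream..-1,+1..+downstream, no position 0).  Ambiguous bases (N) are
excluded from both numerator and denominator, so each profiled row is a
proper distribution over A/C/G/T whenever at least one base was counted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_BASES = "ACGT"


def position_labels(upstream: int, downstream: int) -> list[int]:
    """TSS-relative labels -upstream..-1,+1..+downstream (position 0 skipped)."""
    return list(range(-upstream, 0)) + list(range(1, downstream + 1))


def _char_matrix(sequences: Sequence[str]) -> np.ndarray:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("all sequences must share one aligned length")
    return np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(len(sequences), -1)


def composition_profile(sequences: Sequence[str], upstream: int = 200,
                        downstream: int = 100) -> pd.DataFrame:
    """Column-wise A/C/G/T proportions of TSS-aligned sequences.

    Rows are TSS-relative positions, columns the four bases; every row with
    at least one counted base sums to 1.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("composition profile needs at least one sequence")
    mat = _char_matrix(sequences)
    if mat.shape[1] != upstream + downstream:
        raise ValueError(
            f"sequences are {mat.shape[1]} nt but the window spans {upstream + downstream}"
        )
    counts = np.stack([(mat == b.encode()).sum(axis=0) for b in _BASES], axis=1).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(freqs, index=position_labels(upstream, downstream), columns=list(_BASES))


def initiator_dinucleotide(sequences: Iterable[str], upstream: int = 50) -> pd.Series:
    """Frequency of the 16 dinucleotides at positions (-1, +1) across sequences.

    ``upstream`` locates the TSS within the aligned strings (the -1 base sits
    at string index ``upstream - 1``).  Pairs containing N are excluded; the
    returned proportions sum to 1.
    """
    dinucs = [a + b for a in _BASES for b in _BASES]
    counts = pd.Series(0.0, index=dinucs)
    for seq in sequences:
        if len(seq) < upstream + 1:
            raise ValueError("sequence does not cover positions -1/+1")
        pair = seq[upstream - 1 : upstream + 1]
        if pair in counts.index:
            counts[pair] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous -1/+1 dinucleotides found")
    return counts / total
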