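"""Assembly summary statistics: N50, length summaries and histograms.

N50 is the standard contig N50: the largest length L such that contigs of
length >= L together contain at least half of the assembly's total bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError

DEFAULT_LENGTH_FLOOR = 100


@dataclass
class AssemblyStats:
    n_transcripts: int
    n50: int
    mean_len: int          # rounded half-up to the nearest integer
    max_len: int
    min_len: int
    total_bases: int
    n_over_1kb: int
    n_below_floor: int = 0

    def to_tsv(self) -> str:
        head = "n_transcripts\tn50\tmean_len\tmax_len\tmin_len\ttotal_bases\tn_over_1kb"
        row = (
            f"{self.n_transcripts}\t{self.n50}\t{self.mean_len}\t{self.max_len}\t"
            f"{self.min_len}\t{self.total_bases}\t{self.n_over_1kb}"
        )
        return head + "\n" + row + "\n"


def n50(lengths: Sequence[int]) -> int:
    """Largest L with sum(lengths >= L) >= total/2."""
    if not lengths:
        raise DomainError("n50 of an empty length set")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    return min(lengths)  # unreachable; guards float/rounding misuse


def assembly_stats(
    lengths_or_records: Iterable, length_floor: int = DEFAULT_LENGTH_FLOOR
) -> AssemblyStats:
    """Summary statistics of an assembly.

    Accepts either an iterable of integer lengths or of (id, sequence)
    pairs.  Sequences shorter than length_floor are excluded from every
    statistic and counted in n_below_floor.
    """
    lengths = []
    n_below = 0
    for item in lengths_or_records:
        L = item if isinstance(item, (int, np.integer)) else len(item[1])
        if L < length_floor:
            n_below += 1
        else:
            lengths.append(int(L))
    if not lengths:
        raise DomainError(f"no sequences of length >= {length_floor}")
    total = sum(lengths)
    mean = int(math.floor(total / len(lengths) + 0.5))
    return AssemblyStats(
        n_transcripts=len(lengths),
        n50=n50(lengths),
        mean_len=mean,
        max_len=max(lengths),
        min_len=min(lengths),
        total_bases=total,
        n_over_1kb=sum(1 for L in lengths if L > 1000),
        n_below_floor=n_below,
    )


def histogram(values: Sequence[float], bin_edges: Sequence[float]) -> list[int]:
    """Left-closed right-open binning with a trailing overflow bin.

    Edges must be strictly increasing; values below the first edge are not
    counted (none arise for lengths/coverages >= 0 with edge 0); values at
    or above the last edge land in the overflow bin, so counts conserve the
    total for non-negative data.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise DomainError("bin_edges must be strictly increasing")
    counts = [0] * len(edges)  # len-1 interior bins + overflow
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return counts
    idx = np.searchsorted(edges, arr, side="right") - 1
    for i in idx:
        if i >= 0:
            counts[min(int(i), len(edges) - 1)] += 1
    return counts
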