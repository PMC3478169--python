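"""Read quality control: trimming, length filtering and read-set summaries.

Each read is trimmed to its longest contiguous segment in which every base
has a Phred quality at or above a threshold (default Q13, i.e. an error
probability of about 0.05).  Reads shorter than a minimum length after
trimming (default 25 bp) are discarded; when only one mate of a pair
survives, it is kept as a singleton, mirroring how short-read assemblers
consume paired and unpaired reads separately.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from statistics import median_low
from typing import Iterable, Optional, Sequence

from .errors import FormatError
from . import fio

DEFAULT_PHRED_MIN = 13
DEFAULT_MIN_LEN = 25


@dataclass
class QualityRead:
    """A read with per-base Phred scores (Sanger scale, 0-93)."""

    id: str
    sequence: str
    quals: list[int]
    mate: Optional["QualityRead"] = None

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.sequence):
            raise FormatError(
                f"read {self.id}: {len(self.quals)} quality scores for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def mean_error(self) -> float:
        """Mean per-base error probability, p = 10^(-Q/10) averaged over bases."""
        if not self.quals:
            return 1.0
        return sum(10.0 ** (-q / 10.0) for q in self.quals) / len(self.quals)


@dataclass
class TrimmedReadSet:
    paired: list[tuple[QualityRead, QualityRead]] = field(default_factory=list)
    singletons: list[QualityRead] = field(default_factory=list)
    n_removed: int = 0

    @property
    def n_retained(self) -> int:
        return 2 * len(self.paired) + len(self.singletons)


@dataclass
class ReadQCSummary:
    q20_pct: float
    n_pct: float
    gc_pct: float
    mean_len: float
    median_len: float
    total_reads: int

    def to_tsv(self) -> str:
        head = "q20_pct\tn_pct\tgc_pct\tmean_len\tmedian_len\ttotal_reads"
        row = (
            f"{self.q20_pct:.2f}\t{self.n_pct:.2f}\t{self.gc_pct:.2f}\t"
            f"{self.mean_len:.2f}\t{self.median_len:g}\t{self.total_reads}"
        )
        return head + "\n" + row + "\n"


def trim_read(read: QualityRead, phred_min: int = DEFAULT_PHRED_MIN) -> QualityRead:
    """Trim to the longest run of consecutive bases with Phred >= phred_min.

    Ties between equal-length runs are broken leftmost; a read with no
    qualifying base becomes empty.
    """
    best_start, best_len = 0, 0
    run_start = None
    for i, q in enumerate(read.quals):
        if q >= phred_min:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if run_start is not None and len(read.quals) - run_start > best_len:
        best_start, best_len = run_start, len(read.quals) - run_start
    return QualityRead(
        read.id,
        read.sequence[best_start : best_start + best_len],
        read.quals[best_start : best_start + best_len],
    )


def filter_and_sort(
    pairs: Sequence[tuple[QualityRead, QualityRead]],
    min_len: int = DEFAULT_MIN_LEN,
    phred_min: int = DEFAULT_PHRED_MIN,
) -> TrimmedReadSet:
    """Trim both mates of every pair, then length-filter and re-sort.

    Pairs where both mates survive (length >= min_len) stay paired; pairs
    with exactly one survivor contribute a singleton; removed mates are
    counted individually in n_removed.
    """
    out = TrimmedReadSet()
    for r1, r2 in pairs:
        t1 = trim_read(r1, phred_min)
        t2 = trim_read(r2, phred_min)
        ok1 = len(t1) >= min_len
        ok2 = len(t2) >= min_len
        if ok1 and ok2:
            out.paired.append((t1, t2))
        elif ok1:
            out.singletons.append(t1)
            out.n_removed += 1
        elif ok2:
            out.singletons.append(t2)
            out.n_removed += 1
        else:
            out.n_removed += 2
    return out


def read_set_summary(reads: Iterable[QualityRead]) -> ReadQCSummary:
    """Q20%, N%, GC% and length summary of a read set.

    Q20% is the percentage of reads whose mean per-base error probability is
    strictly below 1%; GC% is computed over non-N bases only; the median is
    the lower median for even counts.
    """
    n_reads = 0
    n_q20 = 0
    n_bases = 0
    n_n = 0
    n_gc = 0
    lengths: list[int] = []
    for r in reads:
        n_reads += 1
        lengths.append(len(r))
        if r.mean_error() < 0.01:
            n_q20 += 1
        for b in r.sequence:
            n_bases += 1
            if b == "N":
                n_n += 1
            elif b in "GC":
                n_gc += 1
    if n_reads == 0:
        return ReadQCSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0)
    non_n = n_bases - n_n
    return ReadQCSummary(
        q20_pct=100.0 * n_q20 / n_reads,
        n_pct=100.0 * n_n / n_bases if n_bases else 0.0,
        gc_pct=100.0 * n_gc / non_n if non_n else 0.0,
        mean_len=n_bases / n_reads,
        median_len=float(median_low(lengths)),
        total_reads=n_reads,
    )


def load_pairs(
    mate1_path: str | os.PathLike, mate2_path: str | os.PathLike
) -> list[tuple[QualityRead, QualityRead]]:
    """Read two mate FASTQ files record-by-record into aligned pairs."""
    pairs = []
    it1 = fio.read_fastq(mate1_path)
    it2 = fio.read_fastq(mate2_path)
    for rec1 in it1:
        try:
            rec2 = next(it2)
        except StopIteration:
            raise FormatError(
                f"{mate2_path}: fewer records than {mate1_path}"
            ) from None
        pairs.append(
            (QualityRead(rec1[0], rec1[1], rec1[2]), QualityRead(rec2[0], rec2[1], rec2[2]))
        )
    if next(it2, None) is not None:
        raise FormatError(f"{mate2_path}: more records than {mate1_path}")
    return pairs


def write_trimmed(
    result: TrimmedReadSet,
    mate1_path: str | os.PathLike,
    mate2_path: str | os.PathLike,
    singleton_path: str | os.PathLike,
) -> None:
    fio.write_fastq(mate1_path, ((r.id, r.sequence, r.quals) for r, _ in result.paired))
    fio.write_fastq(mate2_path, ((r.id, r.sequence, r.quals) for _, r in result.paired))
    fio.write_fastq(singleton_path, ((r.id, r.sequence, r.quals) for r in result.singletons))
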