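"""Coverage-based assembly validation.

Reads are mapped back to the assembled transcripts (by an external aligner;
this module consumes the SAM output) and per-base depth is accumulated.
Three removal rules are applied, in order of precedence:

1. ribosomal-RNA transcripts (identified by a repeat scan or a user list);
2. low coverage: mean depth per base below a floor (default 3);
3. coverage gaps: any base whose depth has dropped to one tenth of the
   transcript's own mean depth or below — the signature of a chimeric join,
   since few fragments span an incorrectly joined region.

Depth counts reference bases consumed by aligned read bases (CIGAR M/=/X).
Deletions and skips (D/N) consume reference without contributing depth;
insertions and clips (I/S/H/P) contribute nothing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

from .errors import DomainError, FormatError, IntegrityError
from . import fio

DEFAULT_MEAN_MIN = 3.0
DEFAULT_GAP_FRACTION = 0.1

_DEPTH_OPS = {0, 7, 8}       # M, =, X: consume reference and add depth
_REF_ONLY_OPS = {2, 3}       # D, N: consume reference, no depth


@dataclass
class CoverageProfile:
    transcript_id: str
    depth: np.ndarray

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    @property
    def min_depth(self) -> int:
        return int(self.depth.min()) if len(self.depth) else 0

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class FilterDecision:
    transcript_id: str
    verdict: str  # keep | low_coverage | coverage_gap | rrna
    trigger_positions: list[int] = field(default_factory=list)


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_low: int = 0
    n_removed_gap: int = 0
    n_removed_rrna: int = 0
    n_kept: int = 0


def depth_from_alignments(
    sam_path: str | os.PathLike, fasta_path: str | os.PathLike
) -> dict[str, CoverageProfile]:
    """Accumulate per-base depth for every transcript from a SAM stream.

    Transcripts with no mapped reads get an all-zero profile.  Unmapped
    records are skipped; every mapped record counts regardless of mapping
    quality, and paired and singleton mappings contribute identically.
    """
    profiles = {
        tid: CoverageProfile(tid, np.zeros(len(seq), dtype=np.int64))
        for tid, seq in fio.read_fasta(fasta_path)
    }
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            tid = rec.reference_name
            prof = profiles.get(tid)
            if prof is None:
                raise IntegrityError(
                    f"{sam_path}: alignment references {tid!r}, absent from "
                    f"{fasta_path}"
                )
            if rec.cigartuples is None:
                raise FormatError(f"{sam_path}: mapped record {rec.query_name} lacks a CIGAR")
            pos = rec.reference_start
            for op, n in rec.cigartuples:
                if op in _DEPTH_OPS:
                    if pos + n > len(prof.depth):
                        raise IntegrityError(
                            f"{sam_path}: {rec.query_name} overruns {tid} "
                            f"({pos + n} > {len(prof.depth)})"
                        )
                    prof.depth[pos : pos + n] += 1
                    pos += n
                elif op in _REF_ONLY_OPS:
                    pos += n
                # I, S, H, P: no reference consumption
    return profiles


def classify_transcript(
    profile: CoverageProfile,
    mean_min: float = DEFAULT_MEAN_MIN,
    gap_fraction: float = DEFAULT_GAP_FRACTION,
    end_margin: int = 0,
) -> FilterDecision:
    """Classify one transcript as keep / low_coverage / coverage_gap.

    The gap rule is inclusive: a base whose depth equals exactly
    gap_fraction x mean triggers it.  end_margin excludes that many bases at
    each end from gap detection (terminal ramp-down regions where depth
    falls off simply because fewer read start positions cover them).
    """
    n = len(profile)
    if n == 0:
        raise DomainError(f"transcript {profile.transcript_id} has zero length")
    mean = profile.mean_depth
    if mean < mean_min:
        return FilterDecision(profile.transcript_id, "low_coverage")
    lo, hi = end_margin, n - end_margin
    if lo < hi:
        window = profile.depth[lo:hi]
        trigger = np.nonzero(window <= gap_fraction * mean)[0] + lo
    else:
        trigger = np.array([], dtype=int)
    if trigger.size:
        return FilterDecision(profile.transcript_id, "coverage_gap", trigger.tolist())
    return FilterDecision(profile.transcript_id, "keep")


def apply_filters(
    profiles: Mapping[str, CoverageProfile],
    rrna_ids: Iterable[str] = (),
    transcripts: Optional[Sequence[tuple[str, str]]] = None,
    mean_min: float = DEFAULT_MEAN_MIN,
    gap_fraction: float = DEFAULT_GAP_FRACTION,
    end_margin: int = 0,
) -> tuple[list[tuple[str, str]], FilterReport, list[FilterDecision]]:
    """Apply rRNA, mean-coverage and coverage-gap filters to an assembly.

    `transcripts` is the ordered (id, sequence) list; if omitted, decisions
    are made for profiles only and the kept list carries empty sequences.
    Verdict precedence is rrna -> low_coverage -> coverage_gap; each
    transcript is counted once under the first matching verdict.
    """
    rrna = set(rrna_ids)
    if transcripts is None:
        transcripts = [(tid, "") for tid in profiles]
    report = FilterReport(n_input=len(transcripts))
    decisions: list[FilterDecision] = []
    kept: list[tuple[str, str]] = []
    for tid, seq in transcripts:
        if tid not in profiles:
            raise IntegrityError(f"no coverage profile for transcript {tid}")
        if tid in rrna:
            d = FilterDecision(tid, "rrna")
        else:
            d = classify_transcript(profiles[tid], mean_min, gap_fraction, end_margin)
        decisions.append(d)
        if d.verdict == "keep":
            report.n_kept += 1
            kept.append((tid, seq))
        elif d.verdict == "rrna":
            report.n_removed_rrna += 1
        elif d.verdict == "low_coverage":
            report.n_removed_low += 1
        else:
            report.n_removed_gap += 1
    return kept, report, decisions


def write_decision_table(decisions: Sequence[FilterDecision], path) -> None:
    """Per-transcript verdicts; trigger positions emitted 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("transcript\tverdict\ttrigger_positions\n")
        for d in decisions:
            pos = ",".join(str(p + 1) for p in d.trigger_positions)
            fh.write(f"{d.transcript_id}\t{d.verdict}\t{pos}\n")


def write_bedgraph(profiles: Mapping[str, CoverageProfile], path) -> None:
    """Per-base depth as BedGraph (0-based half-open, runs merged)."""
    with open(path, "w") as fh:
        for tid, prof in profiles.items():
            d = prof.depth
            if len(d) == 0:
                continue
            starts = np.flatnonzero(np.diff(d) != 0) + 1
            bounds = np.concatenate(([0], starts, [len(d)]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{tid}\t{a}\t{b}\t{int(d[a])}\n")
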