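"""BLAST-based annotation merging and ORF completeness calls.

Transcripts are compared against several reference sets (e.g. a non-
redundant protein database and the UniGene sets of related species); each
search yields 12-column tabular BLAST output.  This module picks the top
hit per query per source, merges sources into an annotated/unannotated
call at an e-value threshold (default 1e-5, inclusive), counts distinct
subject genes to estimate what fraction of a reference transcriptome the
assembly covers, and classifies ORF completeness from a six-frame scan
combined with how much of the subject the hit spans.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import DomainError, FormatError
from .fio import revcomp

DEFAULT_EVALUE_MAX = 1e-5
FULL_LENGTH_SUBJECT_COV = 0.9
PUTATIVE_SUBJECT_COV = 0.5

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    source_db: str = ""


@dataclass
class AnnotationRecord:
    transcript_id: str
    top_hits: dict[str, BlastHit] = field(default_factory=dict)

    @property
    def sources_matched(self) -> list[str]:
        return list(self.top_hits)

    @property
    def annotated(self) -> bool:
        return bool(self.top_hits)


@dataclass
class OrfCall:
    transcript_id: str
    frame: int                  # -3..-1, +1..+3
    orf_start: int              # 1-based on the forward transcript
    orf_end: int
    has_start_codon: bool
    has_stop_codon: bool
    orf_class: str              # full_length | putative_full_length | partial


def parse_blast_tabular(path: str | os.PathLike, source_db: str = "") -> list[BlastHit]:
    """Parse 12-column tabular BLAST output ('-outfmt 6'); '#' comment lines
    are skipped; any other column count is a format error naming the line."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, found {len(cols)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        align_len=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                        source_db=source_db,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def top_hit_per_query(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
    """Best hit per query: lowest e-value, ties by highest bitscore, then
    first occurrence in file order."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[h.query_id] = h
    return best


def build_annotated_set(
    hits_by_source: Mapping[str, Sequence[BlastHit]],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    strict: bool = False,
) -> tuple[dict[str, AnnotationRecord], dict[str, int]]:
    """Merge per-source hits into annotation records.

    A transcript is annotated iff it has a hit meeting the e-value threshold
    in at least one source; the threshold is inclusive (evalue <= evalue_max)
    by default, or strict (<) with strict=True.  Returns the records plus a
    count per source and the union under key '__union__'.
    """
    records: dict[str, AnnotationRecord] = {}
    counts: dict[str, int] = {}
    for source, hits in hits_by_source.items():
        if strict:
            ok = [h for h in hits if h.evalue < evalue_max]
        else:
            ok = [h for h in hits if h.evalue <= evalue_max]
        top = top_hit_per_query(ok)
        counts[source] = len(top)
        for qid, h in top.items():
            rec = records.setdefault(qid, AnnotationRecord(qid))
            rec.top_hits[source] = h
    counts["__union__"] = len(records)
    return records, counts


def count_unique_subjects(
    records: Mapping[str, AnnotationRecord], source_db: str
) -> int:
    """Distinct subject ids among per-transcript top hits in one source."""
    return len(
        {r.top_hits[source_db].subject_id for r in records.values() if source_db in r.top_hits}
    )


def coverage_estimate(unique: int, db_size: int) -> float:
    """Percent of a reference gene set matched by distinct subjects."""
    if db_size <= 0:
        raise DomainError(f"db_size must be positive, got {db_size}")
    return 100.0 * unique / db_size


def write_annotation_table(
    records: Mapping[str, AnnotationRecord], sources: Sequence[str], path
) -> None:
    with open(path, "w") as fh:
        cols = [f"{s}_{c}" for s in sources for c in ("subject", "evalue")]
        fh.write("transcript\tannotated\t" + "\t".join(cols) + "\n")
        for tid in sorted(records):
            rec = records[tid]
            cells = []
            for s in sources:
                h = rec.top_hits.get(s)
                cells += [h.subject_id, f"{h.evalue:.3g}"] if h else ["-", "-"]
            fh.write(f"{tid}\t{int(rec.annotated)}\t" + "\t".join(cells) + "\n")


# --- ORF completeness ----------------------------------------------------

def _longest_orf_in_strand(seq: str) -> tuple[int, int, bool, bool]:
    """Best ORF over the three forward frames of `seq`.

    Candidate ORFs are maximal stop-free codon runs; a run containing an ATG
    is taken from its first ATG.  Returns (start, end) 0-based half-open on
    this strand plus start/stop codon presence; ORFs are ranked by
    (completeness, length).
    """
    best = (0, 0, False, False)

    def rank(c):
        return (c[2] and c[3], c[1] - c[0])

    n = len(seq)
    for frame in range(3):
        run_start = None
        atg = None
        i = frame
        while i + 3 <= n + 3:  # one extra lap to flush the last run
            codon = seq[i : i + 3] if i + 3 <= n else ""
            is_stop = codon in _STOPS
            if codon and not is_stop:
                if run_start is None:
                    run_start = i
                if atg is None and codon == "ATG":
                    atg = i
            if (is_stop or not codon) and run_start is not None:
                end = i + 3 if is_stop else i
                if atg is not None:
                    cand = (atg, end, True, is_stop)
                else:
                    cand = (run_start, end, False, is_stop)
                if rank(cand) > rank(best):
                    best = cand
                run_start = None
                atg = None
            i += 3
    return best


def classify_orf_completeness(
    transcript_id: str,
    sequence: str,
    top_hit: Optional[BlastHit] = None,
    subject_length: Optional[int] = None,
    full_cov: float = FULL_LENGTH_SUBJECT_COV,
    putative_cov: float = PUTATIVE_SUBJECT_COV,
) -> OrfCall:
    """Locate the best ORF over six frames and classify completeness.

    full_length requires an ORF with both a start and a stop codon, and —
    when a reference hit with a known subject length is supplied — the hit
    covering at least full_cov of the subject; coverage in
    [putative_cov, full_cov) gives putative_full_length; anything else is
    partial.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        raise DomainError(f"{transcript_id}: sequence shorter than one codon")
    if any(b not in "ACGTN" for b in seq):
        raise DomainError(f"{transcript_id}: sequence contains non-ACGTN characters")

    fwd = _longest_orf_in_strand(seq)
    rev = _longest_orf_in_strand(revcomp(seq))

    def rank(c):
        return (c[2] and c[3], c[1] - c[0])

    n = len(seq)
    if rank(fwd) >= rank(rev):
        s0, e0, has_start, has_stop = fwd
        frame = (s0 % 3) + 1
        start, end = s0 + 1, e0
    else:
        s0, e0, has_start, has_stop = rev
        frame = -((s0 % 3) + 1)
        start, end = n - e0 + 1, n - s0

    complete = has_start and has_stop
    orf_class = "partial"
    if complete:
        if top_hit is None or subject_length is None:
            orf_class = "full_length"
        else:
            cov = (abs(top_hit.s_end - top_hit.s_start) + 1) / subject_length
            if cov >= full_cov:
                orf_class = "full_length"
            elif cov >= putative_cov:
                orf_class = "putative_full_length"
    return OrfCall(
        transcript_id=transcript_id,
        frame=frame,
        orf_start=start,
        orf_end=end,
        has_start_codon=has_start,
        has_stop_codon=has_stop,
        orf_class=orf_class,
    )
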