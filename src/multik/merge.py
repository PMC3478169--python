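"""Additive multiple-k assembly merging.

A de Bruijn assembler run at several k-mer sizes recovers complementary
transcript sets: low k favours weakly expressed genes, high k resolves
highly expressed ones.  This module takes the per-k assemblies (Oases-style
locus/isoform FASTA), keeps one representative transcript per locus, pools
the representatives from every k, and collapses redundancy by greedy
incremental clustering at a sequence-identity threshold (default 95%),
retaining the longest transcript of each cluster.

Identity between two sequences is defined over a semi-global alignment in
which the shorter sequence is aligned end-to-end against the longer one
(match +1, mismatch -1, gap open -2, gap extend -1, overhangs of the longer
sequence free), as the number of identically aligned bases divided by the
length of the shorter sequence.  Among co-optimal alignments the one with
the most identities is used, so the identity is a well-defined function of
the sequence pair.  Under this convention an exact fragment is 100%
identical to its full-length parent, which is what lets a truncated high-k
contig collapse into the low-k transcript that contains it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigError, DomainError, FormatError, IntegrityError
from . import fio

DEFAULT_IDENTITY_THRESHOLD = 0.95
DEFAULT_MIN_TRANSCRIPT_LEN = 100
PREFILTER_WORD = 11

_HEADER_RE = re.compile(
    r"^Locus_(?P<locus>\w+?)_Transcript_(?P<idx>\d+)/(?P<count>\d+)"
    r"_Confidence_(?P<conf>\d+(?:\.\d+)?)_Length_(?P<len>\d+)$"
)


@dataclass
class AssembledTranscript:
    """One transcript from a single-k assembly, with its header metadata."""

    kmer: int
    locus_id: str
    transcript_index: int
    isoform_count: int
    confidence: float
    declared_length: int
    sequence: str = ""

    @property
    def id(self) -> str:
        return (
            f"Locus_{self.locus_id}_Transcript_{self.transcript_index}/"
            f"{self.isoform_count}_Confidence_{self.confidence:.3f}"
            f"_Length_{self.declared_length}"
        )

    @property
    def merged_id(self) -> str:
        """Globally unique id once assemblies from several k are pooled."""
        return f"{self.kmer}_Locus_{self.locus_id}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ClusterRecord:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    pairwise_identity_to_rep: dict[str, float] = field(default_factory=dict)


@dataclass
class MergedSet:
    transcripts: list[AssembledTranscript]
    clusters: list[ClusterRecord]
    provenance: dict[str, tuple[int, str]]


def parse_oases_header(header: str, kmer: int = 0) -> AssembledTranscript:
    """Parse 'Locus_i_Transcript_j/m_Confidence_c_Length_L' into metadata."""
    m = _HEADER_RE.match(header.strip())
    if m is None:
        raise FormatError(f"unparseable assembler header: {header!r}")
    t = AssembledTranscript(
        kmer=kmer,
        locus_id=m.group("locus"),
        transcript_index=int(m.group("idx")),
        isoform_count=int(m.group("count")),
        confidence=float(m.group("conf")),
        declared_length=int(m.group("len")),
    )
    if t.transcript_index > t.isoform_count:
        raise FormatError(
            f"header {header!r}: transcript index {t.transcript_index} exceeds "
            f"isoform count {t.isoform_count}"
        )
    return t


def load_assembly(
    path, kmer: int, min_len: int = DEFAULT_MIN_TRANSCRIPT_LEN
) -> list[AssembledTranscript]:
    """Load one k-assembly FASTA, validating headers against sequences.

    Transcripts shorter than min_len (default 100 bp, the usual assembler
    reporting floor) are dropped on load.
    """
    out = []
    for header, seq in fio.read_fasta(path):
        t = parse_oases_header(header, kmer=kmer)
        if t.declared_length != len(seq):
            raise IntegrityError(
                f"{path}: header {header!r} declares {t.declared_length} bp "
                f"but sequence has {len(seq)} bp"
            )
        if len(seq) < min_len:
            continue
        t.sequence = seq
        out.append(t)
    return out


def select_representatives(
    transcripts: Iterable[AssembledTranscript],
) -> list[AssembledTranscript]:
    """Pick one transcript per locus: longest, then highest confidence, then
    lowest isoform index.  Output ordered by first appearance of each locus."""
    best: dict[str, AssembledTranscript] = {}
    order: list[str] = []
    for t in transcripts:
        cur = best.get(t.locus_id)
        if cur is None:
            best[t.locus_id] = t
            order.append(t.locus_id)
            continue
        key = (len(t), t.confidence, -t.transcript_index)
        cur_key = (len(cur), cur.confidence, -cur.transcript_index)
        if key > cur_key:
            best[t.locus_id] = t
    return [best[lc] for lc in order]


# Scores and identity counts are packed into one int64 per DP cell as
# score * _PACK + identities, which orders cells lexicographically by
# (score, identities) provided identities stays below _PACK.
_PACK = 1 << 20
_NEG = np.int64(-(1 << 60))

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a normal dependency
    _njit = None


def _dp_kernel_py(xa, ya):  # noqa: C901 - hot loop, kept flat
    n, m = xa.shape[0], ya.shape[0]
    open_cost = 2 * _PACK
    ext = _PACK
    match_gain = _PACK + 1
    mismatch = _PACK
    NEGV = -(1 << 60)
    M = np.full(m + 1, NEGV, dtype=np.int64)
    Ix = np.full(m + 1, NEGV, dtype=np.int64)
    Iy = np.full(m + 1, NEGV, dtype=np.int64)
    M[0] = 0
    for j in range(1, m + 1):
        Iy[j] = -open_cost - ext * (j - 1)
    nM = np.empty(m + 1, dtype=np.int64)
    nIx = np.empty(m + 1, dtype=np.int64)
    nIy = np.empty(m + 1, dtype=np.int64)
    for i in range(n):
        xi = xa[i]
        nM[0] = NEGV
        o = M[0] if M[0] > Iy[0] else Iy[0]
        nIx[0] = o if o > Ix[0] else Ix[0]
        nIy[0] = NEGV
        for j in range(1, m + 1):
            a = M[j - 1]
            if Ix[j - 1] > a:
                a = Ix[j - 1]
            if Iy[j - 1] > a:
                a = Iy[j - 1]
            nM[j] = a + (match_gain if xi == ya[j - 1] else -mismatch)
            o = M[j] if M[j] > Iy[j] else Iy[j]
            if j == m:
                v = o if o > Ix[j] else Ix[j]
            else:
                v1 = o - open_cost
                v2 = Ix[j] - ext
                v = v1 if v1 > v2 else v2
            nIx[j] = v
            b = nM[j - 1] if nM[j - 1] > nIx[j - 1] else nIx[j - 1]
            v1 = b - open_cost
            v2 = nIy[j - 1] - ext
            nIy[j] = v1 if v1 > v2 else v2
        M, nM = nM, M
        Ix, nIx = nIx, Ix
        Iy, nIy = nIy, Iy
    best = M[m]
    if Ix[m] > best:
        best = Ix[m]
    if Iy[m] > best:
        best = Iy[m]
    return best


_dp_kernel = _njit(cache=True)(_dp_kernel_py) if _njit is not None else None


def _semiglobal_score_identities(x: str, y: str) -> tuple[int, int]:
    """Align the shorter y globally against x (match +1, mismatch -1, gap
    open -2, gap extend -1; x-overhangs free) and return the score and the
    maximum identity count among maximum-score alignments."""
    n, m = len(x), len(y)
    xa = np.frombuffer(x.encode(), dtype=np.uint8)
    ya = np.frombuffer(y.encode(), dtype=np.uint8)
    if _dp_kernel is not None:
        final = int(_dp_kernel(xa, ya))
        return final // _PACK, final % _PACK
    open_cost = np.int64(2 * _PACK)
    ext_cost = np.int64(_PACK)
    match_gain = np.int64(_PACK + 1)
    mismatch_cost = np.int64(_PACK)
    j_ramp = np.arange(m + 1, dtype=np.int64) * ext_cost

    M = np.full(m + 1, _NEG)   # x_i aligned to y_j
    Ix = np.full(m + 1, _NEG)  # gap in y: consumes x (free at y's ends)
    Iy = np.full(m + 1, _NEG)  # gap in x: consumes y
    M[0] = 0
    if m:
        Iy[1:] = -open_cost - ext_cost * np.arange(m, dtype=np.int64)
    for i in range(1, n + 1):
        best_prev = np.maximum(M, np.maximum(Ix, Iy))
        sub = np.where(xa[i - 1] == ya, match_gain, -mismatch_cost)
        newM = np.full(m + 1, _NEG)
        newM[1:] = best_prev[:-1] + sub
        open_from = np.maximum(M, Iy)
        newIx = np.maximum(open_from - open_cost, Ix - ext_cost)
        newIx[0] = max(open_from[0], Ix[0])
        newIx[m] = max(open_from[m], Ix[m])
        # Iy[j] = max(max(newM, newIx)[j-1] - open, Iy[j-1] - ext): a
        # running-max recurrence, solved by an accumulated maximum.
        newIy = np.full(m + 1, _NEG)
        if m:
            # opening after y-position t and ending at j costs
            # open + (j-t-1)*ext, so accumulate B_t + t*ext and subtract
            # open + (j-1)*ext.
            src = np.maximum(newM[:-1], newIx[:-1]) + j_ramp[:-1]
            np.maximum.accumulate(src, out=src)
            newIy[1:] = src - open_cost - j_ramp[:-1]
        M, Ix, Iy = newM, newIx, newIy
    final = int(max(M[m], Ix[m], Iy[m]))
    idents = final % _PACK
    score = final // _PACK
    return int(score), int(idents)


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two sequences on the shorter-sequence denominator."""
    if not a or not b:
        raise DomainError("pairwise_identity requires two non-empty sequences")
    longer, shorter = (a, b) if len(a) >= len(b) else (b, a)
    _, idents = _semiglobal_score_identities(longer, shorter)
    return idents / len(shorter)


def _words(seq: str, w: int = PREFILTER_WORD) -> frozenset[str]:
    return frozenset(seq[i : i + w] for i in range(len(seq) - w + 1))


def cluster_and_merge(
    representatives: Sequence[AssembledTranscript],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    prefilter: bool = True,
) -> MergedSet:
    """Greedy incremental clustering of pooled per-k representatives.

    Sequences are visited longest-first (ties by input order); each joins the
    first existing cluster whose representative it matches at or above the
    identity threshold, otherwise it founds a new cluster.  Because of the
    visiting order every cluster representative is its longest member, and
    the merged output is the list of representatives.

    An optional shared-word prefilter skips alignments between sequences with
    no 11-mer in common; at a 95% identity threshold such pairs cannot
    realistically cluster together.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ConfigError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    ordered = sorted(
        range(len(representatives)), key=lambda i: (-len(representatives[i]), i)
    )
    clusters: list[ClusterRecord] = []
    reps: list[AssembledTranscript] = []
    rep_words: list[frozenset[str]] = []
    for i in ordered:
        t = representatives[i]
        if not t.sequence:
            raise DomainError(f"transcript {t.merged_id} has an empty sequence")
        w = _words(t.sequence) if prefilter else frozenset()
        placed = False
        for c, cl in enumerate(clusters):
            if prefilter and rep_words[c].isdisjoint(w):
                continue
            ident = pairwise_identity(reps[c].sequence, t.sequence)
            if ident >= identity_threshold:
                cl.member_ids.append(t.merged_id)
                cl.pairwise_identity_to_rep[t.merged_id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                ClusterRecord(
                    representative_id=t.merged_id,
                    member_ids=[t.merged_id],
                    pairwise_identity_to_rep={t.merged_id: 1.0},
                )
            )
            reps.append(t)
            rep_words.append(w)
    provenance = {t.merged_id: (t.kmer, t.id) for t in reps}
    return MergedSet(transcripts=reps, clusters=clusters, provenance=provenance)


def write_merged(merged: MergedSet, fasta_path, cluster_table_path=None) -> None:
    fio.write_fasta(fasta_path, ((t.merged_id, t.sequence) for t in merged.transcripts))
    if cluster_table_path is not None:
        with open(cluster_table_path, "w") as fh:
            fh.write("cluster\trepresentative\tmember\tidentity_to_representative\n")
            for i, cl in enumerate(merged.clusters):
                for m in cl.member_ids:
                    fh.write(
                        f"{i}\t{cl.representative_id}\t{m}\t"
                        f"{cl.pairwise_identity_to_rep[m]:.4f}\n"
                    )
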