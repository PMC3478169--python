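"""Thin FASTA/FASTQ helpers on top of Biopython's SeqIO.

All sequence files handled by the pipeline are plain text: FASTA for
transcripts and Sanger Phred+33 FASTQ for reads.  Other FASTQ quality
encodings are detected heuristically and rejected.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs; the id is the full header line sans '>'."""
    for rec in SeqIO.parse(str(path), "fasta"):
        # SeqIO splits on whitespace; Oases-style headers contain none, but
        # keep the description to preserve arbitrary headers verbatim.
        yield rec.description, str(rec.seq).upper()


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]], width: int = 70) -> int:
    """Write records as wrapped FASTA; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred_scores) from a Sanger Phred+33 FASTQ.

    Files whose quality distribution is only explicable as Phred+64
    (every score >= 31 with some above the Illumina Phred+33 ceiling of 41)
    are rejected rather than silently mis-scaled.
    """
    min_q, max_q = 94, -1
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if quals:
            min_q = min(min_q, min(quals))
            max_q = max(max_q, max(quals))
        if min_q >= 31 and max_q > 45:
            raise FormatError(
                f"{path}: quality scores all in [{min_q},{max_q}]; this looks "
                "like a Phred+64 encoding, which is not supported"
            )
        yield rec.id, str(rec.seq).upper(), list(quals)


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str, Iterable[int]]]) -> int:
    n = 0
    with open(path, "w") as fh:
        for name, seq, quals in records:
            q = "".join(chr(33 + int(x)) for x in quals)
            fh.write(f"@{name}\n{seq}\n+\n{q}\n")
            n += 1
    return n


def fastq_record(rec_id: str, seq: str, quals: list[int]) -> SeqRecord:
    r = SeqRecord(Seq(seq), id=rec_id, description="")
    r.letter_annotations["phred_quality"] = quals
    return r
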