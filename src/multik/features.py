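"""Microsatellite mining and repeat-landscape summaries.

The microsatellite scanner reports perfect (uninterrupted) tandem repeats
of primitive 2-4 bp motifs that meet per-motif-size unit thresholds —
by default 10 units for di-, 7 for tri- and 5 for tetranucleotide motifs,
so every reported locus spans at least 20 bp.  A run is reported once, under
its canonical motif (the lexicographically smallest rotation of the motif or
of its reverse complement), with maximal extent.

Repeat annotations produced by RepeatMasker (the standard '.out' layout)
are parsed into typed features, summarised into the conventional repeat
category tree (retroelements split into SINE/LINE/LTR subfamilies, DNA
transposons, simple repeats, low complexity, ...), and used to flag
transcripts containing ribosomal RNA.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, FormatError
from .fio import revcomp

DEFAULT_MIN_UNITS = {2: 10, 3: 7, 4: 5}


@dataclass(frozen=True)
class MicrosatelliteHit:
    transcript_id: str
    motif: str          # canonical primitive motif, 2-4 bp
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    unit_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepeatFeature:
    transcript_id: str
    repeat_name: str
    repeat_class_family: str
    start: int          # 1-based inclusive on the transcript
    end: int
    divergence_pct: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter one."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Smallest rotation over the motif and its reverse complement."""
    rc = revcomp(motif)
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def _scan_sequence(
    tid: str, seq: str, min_units: Mapping[int, int]
) -> list[MicrosatelliteHit]:
    hits = []
    n = len(seq)
    for k, min_u in min_units.items():
        i = 0
        while i + 2 * k <= n:
            if seq[i : i + k] == seq[i + k : i + 2 * k] and is_primitive(seq[i : i + k]):
                j = i + 2 * k
                while j < n and seq[j] == seq[j - k]:
                    j += 1
                units = (j - i) // k
                if units >= min_u:
                    hits.append(
                        MicrosatelliteHit(
                            transcript_id=tid,
                            motif=canonical_motif(seq[i : i + k]),
                            start=i + 1,
                            end=i + units * k,
                            unit_count=units,
                        )
                    )
                # next period-k run can share at most k-1 trailing bases
                i = j - k + 1
            else:
                i += 1
    return hits


def scan_microsatellites(
    transcripts: Iterable[tuple[str, str]],
    min_units: Mapping[int, int] = DEFAULT_MIN_UNITS,
) -> list[MicrosatelliteHit]:
    """Scan (id, sequence) pairs for perfect microsatellites.

    Only motif sizes present in min_units are scanned; thresholds must be
    at least 2 units.  Hits are sorted by (transcript, start, motif size).
    """
    for k, u in min_units.items():
        if k < 1 or u < 2:
            raise ConfigError(f"min_units[{k}]={u}: motif size and units must be >= 2")
    hits: list[MicrosatelliteHit] = []
    for tid, seq in transcripts:
        hits.extend(_scan_sequence(tid, seq.upper(), min_units))
    hits.sort(key=lambda h: (h.transcript_id, h.start, len(h.motif)))
    return hits


def write_msat_table(hits: Sequence[MicrosatelliteHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tmotif\tstart\tend\tunit_count\tlength\n")
        for h in hits:
            fh.write(f"{h.transcript_id}\t{h.motif}\t{h.start}\t{h.end}\t{h.unit_count}\t{h.length}\n")


# --- RepeatMasker output -------------------------------------------------

def parse_repeatmasker_out(path: str | os.PathLike) -> list[RepeatFeature]:
    """Parse a RepeatMasker '.out' file (3 header lines, whitespace columns).

    Query coordinates are taken as given (1-based inclusive).  Annotation
    lines must have at least the 14 canonical columns.
    """
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 14:
                raise FormatError(
                    f"{path}:{lineno}: expected >=14 whitespace-delimited "
                    f"columns, found {len(cols)}"
                )
            try:
                feats.append(
                    RepeatFeature(
                        transcript_id=cols[4],
                        repeat_name=cols[9],
                        repeat_class_family=cols[10],
                        start=int(cols[5]),
                        end=int(cols[6]),
                        divergence_pct=float(cols[1]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return feats


# Category tree mirroring the conventional RepeatMasker summary layout.
SUMMARY_CATEGORIES = [
    "Retroelements",
    "SINEs",
    "LINEs",
    "L2/CR1/Rex",
    "RTE/Bov-B",
    "L1/CIN4",
    "LTR elements",
    "Bel/Pao",
    "Ty1/Copia",
    "Gypsy/DIRS1",
    "Retroviral",
    "DNA transposons",
    "Hobo-Activator",
    "Tc1-IS630-Pogo",
    "PiggyBac",
    "Tourist/Harbinger",
    "Unclassified interspersed repeat",
    "Small RNA",
    "Satellites",
    "Simple repeats",
    "Low complexity",
]


def categories_of(class_family: str) -> list[str]:
    """Map a RepeatMasker class/family string onto the summary category
    chain (leaf plus its ancestors); unknown strings fall into
    'Unclassified interspersed repeat'."""
    cf = class_family
    top = cf.split("/")[0]
    if top.startswith("SINE"):
        return ["Retroelements", "SINEs"]
    if top.startswith("LINE"):
        chain = ["Retroelements", "LINEs"]
        if any(s in cf for s in ("CR1", "L2", "Rex")):
            chain.append("L2/CR1/Rex")
        elif any(s in cf for s in ("RTE", "Bov")):
            chain.append("RTE/Bov-B")
        elif any(s in cf for s in ("L1", "CIN4")):
            chain.append("L1/CIN4")
        return chain
    if top.startswith("LTR"):
        chain = ["Retroelements", "LTR elements"]
        if any(s in cf for s in ("Pao", "Bel")):
            chain.append("Bel/Pao")
        elif "Copia" in cf:
            chain.append("Ty1/Copia")
        elif any(s in cf for s in ("Gypsy", "DIRS")):
            chain.append("Gypsy/DIRS1")
        elif "ERV" in cf or "Retrovir" in cf:
            chain.append("Retroviral")
        return chain
    if top.startswith("DNA") or top == "RC":
        chain = ["DNA transposons"]
        if "hAT" in cf or "Hobo" in cf or "Activator" in cf:
            chain.append("Hobo-Activator")
        elif any(s in cf for s in ("TcMar", "Tc1", "IS630", "Pogo")):
            chain.append("Tc1-IS630-Pogo")
        elif "PiggyBac" in cf:
            chain.append("PiggyBac")
        elif any(s in cf for s in ("PIF", "Harbinger", "Tourist")):
            chain.append("Tourist/Harbinger")
        return chain
    if top in ("rRNA", "tRNA", "snRNA", "scRNA", "srpRNA") or cf == "RNA":
        return ["Small RNA"]
    if top.startswith("Satellite"):
        return ["Satellites"]
    if top == "Simple_repeat":
        return ["Simple repeats"]
    if top == "Low_complexity":
        return ["Low complexity"]
    return ["Unclassified interspersed repeat"]


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by 1-based inclusive intervals, overlaps merged."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def summarise_repeats(
    features: Iterable[RepeatFeature], total_bases: int
) -> dict[str, dict[str, float]]:
    """Per-category element counts, occupied bases and percent of assembly.

    Within a category, overlapping features on the same transcript are
    merged before measuring occupied length, so a category never counts a
    base twice; percentages are of total_bases, rounded to 2 decimals.
    """
    if total_bases <= 0:
        raise ConfigError(f"total_bases must be positive, got {total_bases}")
    counts: dict[str, int] = {c: 0 for c in SUMMARY_CATEGORIES}
    spans: dict[str, dict[str, list[tuple[int, int]]]] = {c: {} for c in SUMMARY_CATEGORIES}
    for f in features:
        for cat in categories_of(f.repeat_class_family):
            counts[cat] += 1
            spans[cat].setdefault(f.transcript_id, []).append((f.start, f.end))
    out = {}
    for cat in SUMMARY_CATEGORIES:
        occupied = sum(_union_length(iv) for iv in spans[cat].values())
        out[cat] = {
            "number_of_elements": counts[cat],
            "length_occupied": occupied,
            "percentage_of_sequence": round(100.0 * occupied / total_bases, 2),
        }
    return out


def write_repeat_summary(summary: Mapping[str, Mapping[str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("repeat_type\tnumber_of_elements\tlength_occupied\tpercentage_of_sequence\n")
        for cat in SUMMARY_CATEGORIES:
            row = summary[cat]
            fh.write(
                f"{cat}\t{row['number_of_elements']}\t{row['length_occupied']}\t"
                f"{row['percentage_of_sequence']:.2f}\n"
            )


def flag_rrna(features: Iterable[RepeatFeature]) -> list[str]:
    """Unique ids of transcripts carrying at least one rRNA annotation,
    in order of first appearance."""
    seen: dict[str, None] = {}
    for f in features:
        if "rRNA" in f.repeat_class_family:
            seen.setdefault(f.transcript_id)
    return list(seen)
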