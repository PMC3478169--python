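"""Synthetic data generation for pipeline testing.

Real input to this pipeline is tens of millions of short reads plus six
single-k assemblies from an external assembler.  This module builds a
desk-scale stand-in with known ground truth:

* a truth transcriptome with a long-tailed (discretised power-law)
  expression profile — the high/low coverage dichotomy that motivates
  assembling at multiple k-mer sizes in the first place;
* per-k pseudo-assemblies in which each truth locus appears with some
  capture probability as a possibly truncated copy under an Oases-style
  ``Locus_i_Transcript_j/m_Confidence_c_Length_L`` header, plus planted
  chimeras built from the 5' half of one locus and the 3' half of another;
* paired-end reads drawn from truth transcripts proportional to
  expression x length, with per-cycle Phred scores and quality-driven
  substitution errors.  Chimeric transcripts receive no reads spanning
  their junction (reads come from the two parent loci), so mapping back
  produces the internal coverage trough the coverage filter detects;
* truth-faithful SAM alignments of the simulated reads against any target
  set derived from the pseudo-assemblies, standing in for an external
  mapper.

Every operation is deterministic given the configuration seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .features import canonical_motif
from .fio import revcomp, write_fasta, write_fastq

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class QualityProfile:
    """Per-cycle Phred model.

    Mean quality decays linearly along the read (3' cycles are worse), each
    read carries a normal quality offset (whole reads can be good or bad,
    giving the low-quality tail that trimming removes), and per-base noise
    is added on top.  Scores are clipped to [q_min, q_max].
    """

    mean_start: float = 38.0
    decay_per_cycle: float = 0.35
    read_sd: float = 5.0
    sd: float = 3.0
    q_min: int = 2
    q_max: int = 40


@dataclass(frozen=True)
class SimulationConfig:
    n_loci: int = 100
    length_range: tuple[int, int] = (100, 5750)
    length_log_mean: float = math.log(450.0)
    length_log_sd: float = 0.8
    expression_shape: float = 1.0
    kmer_list: tuple[int, ...] = (21, 25, 29, 33, 37, 41)
    capture_prob_per_k: float = 0.8
    truncation_frac_range: tuple[float, float] = (0.5, 1.0)
    n_read_pairs: int = 50_000
    read_length: int = 50
    insert_mean: float = 200.0
    insert_sd: float = 20.0
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    chimera_rate: float = 0.05
    msat_plant: tuple[tuple[str, int], ...] = (("AC", 12), ("AAG", 8), ("ACGT", 6))
    rrna_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigError(f"n_loci must be positive, got {self.n_loci}")
        lo, hi = self.length_range
        if lo < 100 or hi < lo:
            raise ConfigError(f"length_range must satisfy 100 <= lo <= hi, got {self.length_range}")
        if self.length_log_sd < 0:
            raise ConfigError(f"length_log_sd must be >= 0, got {self.length_log_sd}")
        if self.expression_shape <= 0:
            raise ConfigError(f"expression_shape must be positive, got {self.expression_shape}")
        if list(self.kmer_list) != sorted(set(self.kmer_list)):
            raise ConfigError(f"kmer_list must be strictly increasing, got {self.kmer_list}")
        if not 0.0 <= self.capture_prob_per_k <= 1.0:
            raise ConfigError(f"capture_prob_per_k must be in [0,1], got {self.capture_prob_per_k}")
        tlo, thi = self.truncation_frac_range
        if not (0.0 < tlo <= thi <= 1.0):
            raise ConfigError(
                f"truncation_frac_range must be within (0,1], got {self.truncation_frac_range}"
            )
        if self.n_read_pairs < 0:
            raise ConfigError(f"n_read_pairs must be >= 0, got {self.n_read_pairs}")
        if self.read_length < 1:
            raise ConfigError(f"read_length must be positive, got {self.read_length}")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ConfigError(f"chimera_rate must be in [0,1], got {self.chimera_rate}")
        if not 0.0 <= self.rrna_frac <= 1.0:
            raise ConfigError(f"rrna_frac must be in [0,1], got {self.rrna_frac}")
        for motif, units in self.msat_plant:
            if not (2 <= len(motif) <= 4) or any(b not in "ACGT" for b in motif):
                raise ConfigError(f"msat_plant motif {motif!r} must be 2-4 bp over ACGT")
            if units < 2:
                raise ConfigError(f"msat_plant unit count {units} must be >= 2")
        if len(self.msat_plant) > self.n_loci:
            raise ConfigError("msat_plant: more planted loci than n_loci")


@dataclass(frozen=True)
class Segment:
    """Provenance of one contiguous block of an emitted transcript."""

    truth_id: str
    truth_start: int    # 0-based on the truth transcript
    target_start: int   # 0-based on the emitted transcript
    length: int


@dataclass
class TruthBundle:
    config: SimulationConfig
    truth_transcripts: list[tuple[str, str, float]] = field(default_factory=list)
    k_assembly_files: dict[int, Path] = field(default_factory=dict)
    chimera_ids: list[tuple[int, str]] = field(default_factory=list)
    msat_loci: list[tuple[str, str, int, int]] = field(default_factory=list)
    rrna_ids: list[str] = field(default_factory=list)
    truth_locus_of: dict[tuple[int, str], list[str]] = field(default_factory=dict)
    segments: dict[tuple[int, str], list[Segment]] = field(default_factory=dict)
    junctions: dict[tuple[int, str], int] = field(default_factory=dict)

    def truth_seq(self, truth_id: str) -> str:
        for tid, seq, _ in self.truth_transcripts:
            if tid == truth_id:
                return seq
        raise KeyError(truth_id)


@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    truth_id: str
    start: int      # 0-based on the truth transcript
    length: int


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def generate_truth_transcriptome(config: SimulationConfig) -> TruthBundle:
    """Build the ground-truth transcript set.

    Expression weights follow a discretised power law (weight of the locus
    with rank r proportional to r^-shape), normalised to sum to one and
    assigned to loci in random order.  Planted microsatellites are written
    verbatim at recorded 1-based coordinates with both flanking bases forced
    to break the repeat's periodicity, so each planted locus is a maximal
    perfect repeat recoverable by the scanner.  A fraction of loci is tagged
    as ribosomal.
    """
    rng = _rng(config, 0)
    lo, hi = config.length_range
    n = config.n_loci
    # short-skewed transcript lengths (lognormal, clipped to length_range),
    # matching the shape of real assembled-transcript length distributions;
    # a degenerate range (lo == hi) yields constant lengths
    raw = rng.lognormal(config.length_log_mean, config.length_log_sd, size=n)
    lengths = np.clip(np.rint(raw).astype(int), lo, hi)
    seqs = [_random_seq(rng, int(L)) for L in lengths]

    ranks = rng.permutation(n) + 1
    weights = ranks.astype(float) ** (-config.expression_shape)
    weights /= weights.sum()

    ids = [f"tx{i:04d}" for i in range(n)]
    bundle = TruthBundle(config=config)

    # plant microsatellites on distinct loci, longest transcripts first so
    # the insert (plus flanks) always fits
    order = np.argsort(-lengths)
    for slot, (motif, units) in enumerate(config.msat_plant):
        i = int(order[slot])
        plant = motif * units
        L = int(lengths[i])
        if L < len(plant) + 2:
            raise ConfigError(
                f"msat_plant ({motif},{units}): no transcript long enough to host it"
            )
        pos = int(rng.integers(1, L - len(plant)))  # keep one flank base each side
        arr = seqs[i]
        plant_codes = np.array([("ACGT").index(b) for b in plant])
        arr[pos : pos + len(plant)] = plant_codes
        k = len(motif)
        # break periodicity at both flanks
        left_avoid = plant_codes[k - 1]
        right_avoid = plant_codes[0]
        arr[pos - 1] = (left_avoid + 1 + rng.integers(0, 3)) % 4
        arr[pos + len(plant)] = (right_avoid + 1 + rng.integers(0, 3)) % 4
        bundle.msat_loci.append((ids[i], canonical_motif(motif), pos + 1, units))

    for i in range(n):
        seq = "".join(_BASES[seqs[i]])
        bundle.truth_transcripts.append((ids[i], seq, float(weights[i])))

    n_rrna = int(round(config.rrna_frac * n))
    if n_rrna:
        picks = rng.choice(n, size=n_rrna, replace=False)
        bundle.rrna_ids = [ids[int(i)] for i in sorted(picks)]
    return bundle


def write_truth_fasta(bundle: TruthBundle, path) -> None:
    write_fasta(path, ((tid, seq) for tid, seq, _ in bundle.truth_transcripts))


def simulate_multik_assemblies(
    bundle: TruthBundle, config: SimulationConfig, outdir
) -> TruthBundle:
    """Emit one pseudo-assembly FASTA per k-mer size.

    Each truth locus is captured in a given k-assembly with probability
    capture_prob_per_k, as one to three isoforms, each keeping a contiguous
    substring (fraction drawn from truncation_frac_range, anchor uniform).
    On top of the captured loci, a binomial number of chimeric transcripts
    is added per assembly: 5' half of one parent joined to the 3' half of
    another, junction recorded 0-based.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = bundle.truth_transcripts
    for k in config.kmer_list:
        rng = _rng(config, 1, k)
        records: list[tuple[str, str]] = []
        locus_no = 0
        n_captured = 0
        for tid, seq, _ in truth:
            if rng.random() >= config.capture_prob_per_k:
                continue
            n_captured += 1
            locus_no += 1
            m = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
            for j in range(1, m + 1):
                frac = rng.uniform(*config.truncation_frac_range)
                keep = min(len(seq), max(100, int(round(frac * len(seq)))))
                start = int(rng.integers(0, len(seq) - keep + 1))
                sub = seq[start : start + keep]
                conf = round(1.0 - rng.random(), 3)  # uniform (0, 1]
                header = (
                    f"Locus_{locus_no}_Transcript_{j}/{m}"
                    f"_Confidence_{conf:.3f}_Length_{len(sub)}"
                )
                records.append((header, sub))
                bundle.truth_locus_of[(k, header)] = [tid]
                bundle.segments[(k, header)] = [Segment(tid, start, 0, keep)]
        n_chim = int(rng.binomial(n_captured, config.chimera_rate)) if n_captured else 0
        for _ in range(n_chim):
            ia, ib = rng.choice(len(truth), size=2, replace=False)
            tid_a, seq_a, _ = truth[int(ia)]
            tid_b, seq_b, _ = truth[int(ib)]
            half_a = seq_a[: (len(seq_a) + 1) // 2]
            b_from = len(seq_b) // 2
            half_b = seq_b[b_from:]
            fused = half_a + half_b
            locus_no += 1
            conf = round(1.0 - rng.random(), 3)
            header = (
                f"Locus_{locus_no}_Transcript_1/1"
                f"_Confidence_{conf:.3f}_Length_{len(fused)}"
            )
            records.append((header, fused))
            bundle.chimera_ids.append((k, header))
            bundle.truth_locus_of[(k, header)] = [tid_a, tid_b]
            bundle.junctions[(k, header)] = len(half_a)
            bundle.segments[(k, header)] = [
                Segment(tid_a, 0, 0, len(half_a)),
                Segment(tid_b, b_from, len(half_a), len(half_b)),
            ]
        path = outdir / f"assembly_k{k}.fasta"
        write_fasta(path, records)
        bundle.k_assembly_files[k] = path
    return bundle


def simulate_reads(
    bundle: TruthBundle, config: SimulationConfig, outdir
) -> tuple[Path, Path, Path, list[ReadOrigin]]:
    """Simulate expression-weighted paired-end reads from truth transcripts.

    Fragments are sampled proportional to expression weight x length with a
    normal insert size; mate 1 is the fragment's 5' end, mate 2 the reverse
    complement of its 3' end.  Per-base Phred scores follow the per-cycle
    quality profile and substitution errors are injected at rate
    10^(-Q/10).  Returns (mate1, mate2, singleton, origins); the singleton
    file is empty (unpaired reads arise downstream, from trimming).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 2)
    rl = config.read_length
    qp = config.quality_profile
    truth = bundle.truth_transcripts
    usable = [i for i, (_, seq, _) in enumerate(truth) if len(seq) >= rl]
    p = np.array([truth[i][2] * len(truth[i][1]) for i in usable], dtype=float)
    n = config.n_read_pairs

    mate1_path = outdir / "reads_1.fastq"
    mate2_path = outdir / "reads_2.fastq"
    single_path = outdir / "reads_singleton.fastq"
    origins: list[ReadOrigin] = []

    if n == 0 or not usable or p.sum() <= 0:
        for path in (mate1_path, mate2_path, single_path):
            path.write_text("")
        return mate1_path, mate2_path, single_path, origins

    p /= p.sum()
    picks = rng.choice(len(usable), size=n, p=p)
    inserts_raw = rng.normal(config.insert_mean, config.insert_sd, size=n)
    cycles = np.arange(rl)
    q_mean = qp.mean_start - qp.decay_per_cycle * cycles
    read_offset = rng.normal(0.0, qp.read_sd, size=(2 * n, 1))
    quals = rng.normal(q_mean[None, :] + read_offset, qp.sd, size=(2 * n, rl))
    quals = np.clip(np.rint(quals), qp.q_min, qp.q_max).astype(int)
    err_prob = 10.0 ** (-quals / 10.0)
    err_mask = rng.random((2 * n, rl)) < err_prob
    err_shift = rng.integers(1, 4, size=(2 * n, rl))

    recs1, recs2 = [], []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for r in range(n):
        i = usable[int(picks[r])]
        tid, seq, _ = truth[i]
        L = len(seq)
        insert = int(np.clip(round(inserts_raw[r]), rl, L))
        start = int(rng.integers(0, L - insert + 1))
        frag1 = seq[start : start + rl]
        frag2 = revcomp(seq[start + insert - rl : start + insert])
        rid = f"frag{r}"
        out = []
        for mate, frag in ((0, frag1), (1, frag2)):
            row = 2 * r + mate
            if err_mask[row].any():
                chars = list(frag)
                for pos in np.nonzero(err_mask[row])[0]:
                    b = chars[pos]
                    if b in base_idx:
                        chars[pos] = "ACGT"[(base_idx[b] + err_shift[row, pos]) % 4]
                frag = "".join(chars)
            out.append((f"{rid}/{mate + 1}", frag, quals[row].tolist()))
        recs1.append(out[0])
        recs2.append(out[1])
        origins.append(ReadOrigin(f"{rid}/1", tid, start, rl))
        origins.append(ReadOrigin(f"{rid}/2", tid, start + insert - rl, rl))

    write_fastq(mate1_path, recs1)
    write_fastq(mate2_path, recs2)
    single_path.write_text("")
    return mate1_path, mate2_path, single_path, origins


def write_truth_alignments(
    bundle: TruthBundle,
    targets: Mapping[str, tuple[int, str]],
    target_lengths: Mapping[str, int],
    origins: Sequence[ReadOrigin],
    out_sam,
) -> int:
    """Write truth-faithful SAM alignments of simulated reads to targets.

    ``targets`` maps each target transcript id to its (kmer, original
    header) provenance in the bundle.  A read maps to a target wherever the
    read's source interval on its truth transcript lies entirely inside one
    of the target's provenance segments; multi-mapping records are emitted
    for every such target.  Reads drawn from a chimera's parents therefore
    cover the chimera's two halves but never its junction.
    """
    by_truth: dict[str, list[tuple[str, Segment]]] = {}
    for target_id, key in targets.items():
        for seg in bundle.segments[key]:
            by_truth.setdefault(seg.truth_id, []).append((target_id, seg))
    n = 0
    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for tid in targets:
            fh.write(f"@SQ\tSN:{tid}\tLN:{target_lengths[tid]}\n")
        for o in origins:
            for target_id, seg in by_truth.get(o.truth_id, ()):
                if o.start >= seg.truth_start and o.start + o.length <= seg.truth_start + seg.length:
                    pos = seg.target_start + (o.start - seg.truth_start) + 1
                    fh.write(
                        f"{o.read_id}\t0\t{target_id}\t{pos}\t255\t{o.length}M\t*\t0\t0\t*\t*\n"
                    )
                    n += 1
    return n


def write_manifest(bundle: TruthBundle, path) -> None:
    """Machine-readable truth manifest (tab-separated, one record per row)."""
    with open(path, "w") as fh:
        fh.write("record\tfield1\tfield2\tfield3\tfield4\n")
        for tid, seq, w in bundle.truth_transcripts:
            fh.write(f"truth\t{tid}\t{len(seq)}\t{w:.6e}\t\n")
        for tid, motif, start, units in bundle.msat_loci:
            fh.write(f"msat\t{tid}\t{motif}\t{start}\t{units}\n")
        for tid in bundle.rrna_ids:
            fh.write(f"rrna\t{tid}\t\t\t\n")
        for (k, header), loci in bundle.truth_locus_of.items():
            fh.write(f"assembled\t{k}\t{header}\t{','.join(loci)}\t\n")
        for (k, header) in bundle.chimera_ids:
            fh.write(f"chimera\t{k}\t{header}\t{bundle.junctions[(k, header)]}\t\n")
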