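"""Pipeline orchestration and consolidated reporting.

Stage order mirrors the processing of a multi-k short-read transcriptome
project: read trimming -> (external assembly) -> per-locus representative
selection -> additive multiple-k merge -> coverage validation and rRNA
removal -> repeat/microsatellite scans -> annotation -> summary statistics.

The consolidated report reproduces the shape of a per-assembly summary
table: one Initial and one Representative row per k-mer size, then Merged
and Final rows, and asserts the bookkeeping identity

    final = merged - removed_by_coverage - removed_as_rRNA
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import annotate as annotate_mod
from . import coverage as coverage_mod
from . import features as features_mod
from . import merge as merge_mod
from . import readqc as readqc_mod
from . import simulate as simulate_mod
from . import stats as stats_mod
from .errors import ConfigError, IntegrityError


@dataclass
class ReportRow:
    kmer: Optional[int]
    stage: str
    n_transcripts: int
    n50: int
    mean_len: int
    max_len: int
    total_bases: int


@dataclass
class PipelineReport:
    rows: list[ReportRow] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def add_stats(self, kmer: Optional[int], stage: str, st: stats_mod.AssemblyStats) -> None:
        self.rows.append(
            ReportRow(kmer, stage, st.n_transcripts, st.n50, st.mean_len, st.max_len, st.total_bases)
        )

    def to_tsv(self) -> str:
        out = ["kmer\tstage\tn_transcripts\tn50\tmean_length\tmax_length\ttotal_bases"]
        for r in self.rows:
            k = "" if r.kmer is None else str(r.kmer)
            out.append(
                f"{k}\t{r.stage}\t{r.n_transcripts}\t{r.n50}\t{r.mean_len}\t"
                f"{r.max_len}\t{r.total_bases}"
            )
        return "\n".join(out) + "\n"

    def to_text(self) -> str:
        head = f"{'kmer':>5} {'stage':<16} {'n':>8} {'N50':>7} {'mean':>7} {'max':>7} {'bases':>12}"
        lines = [head]
        for r in self.rows:
            k = "" if r.kmer is None else str(r.kmer)
            lines.append(
                f"{k:>5} {r.stage:<16} {r.n_transcripts:>8} {r.n50:>7} "
                f"{r.mean_len:>7} {r.max_len:>7} {r.total_bases:>12}"
            )
        if self.log:
            lines += ["", *self.log]
        return "\n".join(lines) + "\n"


def check_final_arithmetic(
    n_merged: int, n_removed_coverage: int, n_removed_rrna: int, n_final: int
) -> bool:
    """The merged/removed/final bookkeeping identity."""
    return n_merged - n_removed_coverage - n_removed_rrna == n_final


@dataclass
class SyntheticRunResult:
    bundle: simulate_mod.TruthBundle
    raw_summary: readqc_mod.ReadQCSummary
    trimmed: readqc_mod.TrimmedReadSet
    trimmed_summary: readqc_mod.ReadQCSummary
    merged: merge_mod.MergedSet
    filter_report: coverage_mod.FilterReport
    decisions: list[coverage_mod.FilterDecision]
    kept: list[tuple[str, str]]
    msat_hits: list[features_mod.MicrosatelliteHit]
    final_stats: stats_mod.AssemblyStats
    report: PipelineReport


def run_synthetic_pipeline(
    config: simulate_mod.SimulationConfig,
    outdir,
    end_margin: Optional[int] = None,
) -> SyntheticRunResult:
    """Generate a synthetic study and push it through every pipeline stage.

    end_margin for the coverage-gap rule defaults to the read length:
    simulated coverage ramps down over the terminal read-length of every
    transcript simply because fewer fragments can start there, and the gap
    rule is meant for internal troughs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if end_margin is None:
        end_margin = config.read_length
    report = PipelineReport()

    # --- synthetic study ---------------------------------------------
    bundle = simulate_mod.generate_truth_transcriptome(config)
    simulate_mod.write_truth_fasta(bundle, outdir / "truth.fasta")
    simulate_mod.simulate_multik_assemblies(bundle, config, outdir)
    m1, m2, _single, origins = simulate_mod.simulate_reads(bundle, config, outdir)
    simulate_mod.write_manifest(bundle, outdir / "truth_manifest.tsv")

    # --- read QC ------------------------------------------------------
    pairs = readqc_mod.load_pairs(m1, m2)
    raw_summary = readqc_mod.read_set_summary(r for pair in pairs for r in pair)
    trimmed = readqc_mod.filter_and_sort(pairs)
    trimmed_summary = readqc_mod.read_set_summary(
        [r for pair in trimmed.paired for r in pair] + trimmed.singletons
    )
    readqc_mod.write_trimmed(
        trimmed,
        outdir / "trimmed_1.fastq",
        outdir / "trimmed_2.fastq",
        outdir / "trimmed_singleton.fastq",
    )
    report.log.append(
        f"read_qc: {2 * len(pairs)} reads in, {trimmed.n_retained} retained "
        f"({len(trimmed.paired)} pairs, {len(trimmed.singletons)} singletons), "
        f"{trimmed.n_removed} removed"
    )

    # --- representative selection and multiple-k merge ---------------
    all_reps: list[merge_mod.AssembledTranscript] = []
    for k, path in bundle.k_assembly_files.items():
        assembly = merge_mod.load_assembly(path, kmer=k)
        report.add_stats(k, "Initial", stats_mod.assembly_stats(len(t) for t in assembly))
        reps = merge_mod.select_representatives(assembly)
        report.add_stats(k, "Representative", stats_mod.assembly_stats(len(t) for t in reps))
        all_reps.extend(reps)
    merged = merge_mod.cluster_and_merge(all_reps)
    merge_mod.write_merged(merged, outdir / "merged.fasta", outdir / "clusters.tsv")
    merged_records = [(t.merged_id, t.sequence) for t in merged.transcripts]
    report.add_stats(None, "Merged", stats_mod.assembly_stats(merged_records))
    report.log.append(
        f"multik_merge: {len(all_reps)} representatives from "
        f"{len(bundle.k_assembly_files)} assemblies -> {len(merged.transcripts)} merged"
    )

    # --- coverage validation and rRNA removal ------------------------
    targets = {t.merged_id: (t.kmer, t.id) for t in merged.transcripts}
    target_lengths = {t.merged_id: len(t) for t in merged.transcripts}
    sam_path = outdir / "mapped.sam"
    simulate_mod.write_truth_alignments(bundle, targets, target_lengths, origins, sam_path)
    profiles = coverage_mod.depth_from_alignments(sam_path, outdir / "merged.fasta")
    rrna_truth = set(bundle.rrna_ids)
    rrna_ids = [
        t.merged_id
        for t in merged.transcripts
        if set(bundle.truth_locus_of[(t.kmer, t.id)]) & rrna_truth
    ]
    kept, filt_report, decisions = coverage_mod.apply_filters(
        profiles, rrna_ids, merged_records, end_margin=end_margin
    )
    coverage_mod.write_decision_table(decisions, outdir / "coverage_decisions.tsv")
    n_removed_cov = filt_report.n_removed_low + filt_report.n_removed_gap
    if not check_final_arithmetic(
        filt_report.n_input, n_removed_cov, filt_report.n_removed_rrna, filt_report.n_kept
    ):
        raise IntegrityError("coverage filter bookkeeping does not balance")
    report.log.append(
        f"coverage_qc: {filt_report.n_input} in, {n_removed_cov} removed by "
        f"coverage, {filt_report.n_removed_rrna} removed as rRNA, {filt_report.n_kept} kept"
    )

    # --- final set, scans, statistics ---------------------------------
    from . import fio

    fio.write_fasta(outdir / "final.fasta", kept)
    msat_hits = features_mod.scan_microsatellites(kept)
    features_mod.write_msat_table(msat_hits, outdir / "microsatellites.tsv")
    final_stats = stats_mod.assembly_stats(kept)
    report.add_stats(None, "Final", final_stats)

    (outdir / "report.tsv").write_text(report.to_tsv())
    (outdir / "report.txt").write_text(report.to_text())
    return SyntheticRunResult(
        bundle=bundle,
        raw_summary=raw_summary,
        trimmed=trimmed,
        trimmed_summary=trimmed_summary,
        merged=merged,
        filter_report=filt_report,
        decisions=decisions,
        kept=kept,
        msat_hits=msat_hits,
        final_stats=final_stats,
        report=report,
    )


# --- file-driven pipeline -------------------------------------------------

_STAGE_INPUTS = {
    "trim": ("mate1", "mate2"),
    "merge": ("assemblies",),       # mapping kmer -> fasta path
    "coverage": ("sam", "fasta"),
    "scan": ("fasta",),
    "repeats": ("repeatmasker_out", "fasta"),
    "stats": ("fasta",),
}


def run_pipeline(config: Mapping | str | os.PathLike, outdir=None) -> PipelineReport:
    """Run the requested stages on user-supplied files.

    ``config`` is a mapping (or path to a flat YAML file) with a ``stages``
    list and per-stage input paths; missing inputs for any requested stage
    raise a configuration error before any work is done.  Each stage writes
    its outputs into ``outdir`` and appends a log line with input/output
    counts.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    stages = config.get("stages")
    if not stages:
        raise ConfigError("config field 'stages' is missing or empty")
    for st in stages:
        if st not in _STAGE_INPUTS:
            raise ConfigError(f"unknown stage {st!r}")
        for key in _STAGE_INPUTS[st]:
            if key not in config:
                raise ConfigError(f"stage {st!r} requires config field {key!r}")
    outdir = Path(outdir if outdir is not None else config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()

    from . import fio

    if "trim" in stages:
        pairs = readqc_mod.load_pairs(config["mate1"], config["mate2"])
        trimmed = readqc_mod.filter_and_sort(
            pairs,
            min_len=int(config.get("min_len", readqc_mod.DEFAULT_MIN_LEN)),
            phred_min=int(config.get("phred_min", readqc_mod.DEFAULT_PHRED_MIN)),
        )
        readqc_mod.write_trimmed(
            trimmed,
            outdir / "trimmed_1.fastq",
            outdir / "trimmed_2.fastq",
            outdir / "trimmed_singleton.fastq",
        )
        summary = readqc_mod.read_set_summary(
            [r for pair in trimmed.paired for r in pair] + trimmed.singletons
        )
        (outdir / "readqc_summary.tsv").write_text(summary.to_tsv())
        report.log.append(
            f"trim: {2 * len(pairs)} reads in, {trimmed.n_retained} retained, "
            f"{trimmed.n_removed} removed"
        )

    merged_fasta = config.get("fasta")
    if "merge" in stages:
        all_reps = []
        for k, path in sorted(config["assemblies"].items()):
            assembly = merge_mod.load_assembly(path, kmer=int(k))
            report.add_stats(int(k), "Initial", stats_mod.assembly_stats(len(t) for t in assembly))
            reps = merge_mod.select_representatives(assembly)
            report.add_stats(int(k), "Representative", stats_mod.assembly_stats(len(t) for t in reps))
            all_reps.extend(reps)
        merged = merge_mod.cluster_and_merge(
            all_reps,
            identity_threshold=float(
                config.get("identity_threshold", merge_mod.DEFAULT_IDENTITY_THRESHOLD)
            ),
        )
        merge_mod.write_merged(merged, outdir / "merged.fasta", outdir / "clusters.tsv")
        report.add_stats(
            None, "Merged", stats_mod.assembly_stats((t.merged_id, t.sequence) for t in merged.transcripts)
        )
        report.log.append(f"merge: {len(all_reps)} representatives -> {len(merged.transcripts)}")
        merged_fasta = outdir / "merged.fasta"

    if "coverage" in stages:
        profiles = coverage_mod.depth_from_alignments(config["sam"], merged_fasta)
        rrna_ids = []
        if config.get("rrna_list"):
            rrna_ids = Path(config["rrna_list"]).read_text().split()
        records = list(fio.read_fasta(merged_fasta))
        kept, filt, decisions = coverage_mod.apply_filters(
            profiles,
            rrna_ids,
            records,
            mean_min=float(config.get("mean_min", coverage_mod.DEFAULT_MEAN_MIN)),
            gap_fraction=float(config.get("gap_fraction", coverage_mod.DEFAULT_GAP_FRACTION)),
            end_margin=int(config.get("end_margin", 0)),
        )
        fio.write_fasta(outdir / "final.fasta", kept)
        coverage_mod.write_decision_table(decisions, outdir / "coverage_decisions.tsv")
        n_cov = filt.n_removed_low + filt.n_removed_gap
        if not check_final_arithmetic(filt.n_input, n_cov, filt.n_removed_rrna, filt.n_kept):
            raise IntegrityError("coverage filter bookkeeping does not balance")
        report.add_stats(None, "Final", stats_mod.assembly_stats(kept))
        report.log.append(
            f"coverage: {filt.n_input} in, {n_cov} coverage-removed, "
            f"{filt.n_removed_rrna} rRNA-removed, {filt.n_kept} kept"
        )
        merged_fasta = outdir / "final.fasta"

    if "scan" in stages:
        records = list(fio.read_fasta(merged_fasta))
        hits = features_mod.scan_microsatellites(records)
        features_mod.write_msat_table(hits, outdir / "microsatellites.tsv")
        report.log.append(f"scan: {len(hits)} microsatellites in {len(records)} transcripts")

    if "repeats" in stages:
        feats = features_mod.parse_repeatmasker_out(config["repeatmasker_out"])
        total = sum(len(seq) for _, seq in fio.read_fasta(merged_fasta))
        summary = features_mod.summarise_repeats(feats, total)
        features_mod.write_repeat_summary(summary, outdir / "repeat_summary.tsv")
        report.log.append(f"repeats: {len(feats)} features summarised over {total} bases")

    if "stats" in stages:
        st = stats_mod.assembly_stats(fio.read_fasta(merged_fasta))
        (outdir / "assembly_stats.tsv").write_text(st.to_tsv())
        report.add_stats(None, "Stats", st)
        report.log.append(f"stats: {st.n_transcripts} transcripts, N50 {st.n50}")

    (outdir / "report.tsv").write_text(report.to_tsv())
    (outdir / "report.txt").write_text(report.to_text())
    return report
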