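"""Per-base depth accumulation and coverage-based filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multik.coverage import (
    CoverageProfile,
    apply_filters,
    classify_transcript,
    depth_from_alignments,
)
from multik.errors import DomainError, IntegrityError
from multik import fio, merge as merge_mod, pipeline
from multik.simulate import simulate_reads, simulate_multik_assemblies, generate_truth_transcriptome, write_truth_alignments


def _sam(tmp_path, refs, records):
    path = tmp_path / "aln.sam"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in refs:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, ref, pos, cigar in records:
            fh.write(f"{qname}\t{flag}\t{ref}\t{pos}\t255\t{cigar}\t*\t0\t0\t*\t*\n")
    fasta = tmp_path / "ref.fasta"
    fio.write_fasta(fasta, [(name, "A" * length) for name, length in refs])
    return path, fasta


class TestDepthFromAlignments:
    def test_simple_match(self, tmp_path):
        sam, fasta = _sam(tmp_path, [("t1", 100)], [("r1", 0, "t1", 1, "50M")])
        prof = depth_from_alignments(sam, fasta)["t1"]
        assert prof.depth[:50].tolist() == [1] * 50
        assert prof.depth[50:].sum() == 0

    def test_insertion_consumes_no_reference(self, tmp_path):
        sam, fasta = _sam(tmp_path, [("t1", 100)], [("r1", 0, "t1", 1, "10M5I10M")])
        prof = depth_from_alignments(sam, fasta)["t1"]
        assert int(prof.depth.sum()) == 20
        assert prof.depth[:20].tolist() == [1] * 20

    def test_deletion_consumes_reference_without_depth(self, tmp_path):
        sam, fasta = _sam(tmp_path, [("t1", 100)], [("r1", 0, "t1", 1, "10M5D10M")])
        prof = depth_from_alignments(sam, fasta)["t1"]
        assert prof.depth[:10].tolist() == [1] * 10
        assert prof.depth[10:15].tolist() == [0] * 5
        assert prof.depth[15:25].tolist() == [1] * 10

    def test_soft_clips_ignored(self, tmp_path):
        sam, fasta = _sam(tmp_path, [("t1", 100)], [("r1", 0, "t1", 1, "5S20M5S")])
        prof = depth_from_alignments(sam, fasta)["t1"]
        assert int(prof.depth.sum()) == 20

    def test_empty_sam_gives_zero_profiles(self, tmp_path):
        sam, fasta = _sam(tmp_path, [("t1", 80), ("t2", 120)], [])
        profiles = depth_from_alignments(sam, fasta)
        assert {tid: int(p.depth.sum()) for tid, p in profiles.items()} == {"t1": 0, "t2": 0}

    def test_unknown_reference_rejected(self, tmp_path):
        sam, fasta = _sam(tmp_path, [("t1", 100)], [])
        sam2 = tmp_path / "bad.sam"
        sam2.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:tX\tLN:100\nr1\t0\ttX\t1\t255\t50M\t*\t0\t0\t*\t*\n"
        )
        with pytest.raises(IntegrityError, match="tX"):
            depth_from_alignments(sam2, fasta)


class TestClassifyTranscript:
    def test_mean_just_below_three_is_low_coverage(self):
        depth = np.array([3] * 360 + [2] * 40)  # mean 2.9
        d = classify_transcript(CoverageProfile("t", depth))
        assert d.verdict == "low_coverage"

    def test_mean_exactly_three_is_kept(self):
        d = classify_transcript(CoverageProfile("t", np.full(400, 3)))
        assert d.verdict == "keep"

    def test_gap_rule_is_inclusive_at_one_tenth(self):
        depth = np.array([33] * 90 + [3] * 10)  # mean 30.0, 3 == mean/10
        d = classify_transcript(CoverageProfile("t", depth))
        assert d.verdict == "coverage_gap"
        assert d.trigger_positions == list(range(90, 100))

    def test_single_base_trough_detected(self):
        depth = np.full(100, 31)
        depth[50] = 2
        prof = CoverageProfile("t", depth)
        d = classify_transcript(prof)
        assert d.verdict == "coverage_gap" and d.trigger_positions == [50]

    def test_uniform_coverage_kept(self):
        d = classify_transcript(CoverageProfile("t", np.full(500, 20)))
        assert d.verdict == "keep"

    def test_end_margin_excludes_terminal_rampdown(self):
        depth = np.concatenate([np.arange(1, 51), np.full(400, 50), np.arange(50, 0, -1)])
        assert classify_transcript(CoverageProfile("t", depth)).verdict == "coverage_gap"
        assert (
            classify_transcript(CoverageProfile("t", depth), end_margin=50).verdict == "keep"
        )

    def test_zero_length_rejected(self):
        with pytest.raises(DomainError):
            classify_transcript(CoverageProfile("t", np.array([], dtype=int)))

    @given(
        st.lists(st.integers(0, 200), min_size=5, max_size=60),
        st.integers(2, 20),
    )
    @settings(max_examples=150, deadline=None)
    def test_gap_verdict_is_scale_invariant(self, depth, factor):
        base = CoverageProfile("t", np.array(depth))
        scaled = CoverageProfile("t", np.array(depth) * factor)
        v1 = classify_transcript(base, mean_min=0.0).verdict
        v2 = classify_transcript(scaled, mean_min=0.0).verdict
        assert v1 == v2

    @given(st.lists(st.integers(0, 50), min_size=5, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_raising_mean_floor_never_rescues(self, depth):
        prof = CoverageProfile("t", np.array(depth))
        removed_lo = classify_transcript(prof, mean_min=2.0).verdict != "keep"
        removed_hi = classify_transcript(prof, mean_min=5.0).verdict != "keep"
        assert removed_hi or not removed_lo


class TestApplyFilters:
    def _profiles(self, spec):
        return {tid: CoverageProfile(tid, np.array(d)) for tid, d in spec.items()}

    def test_rrna_precedence_over_depth(self):
        profiles = self._profiles({"t1": [100] * 200})
        kept, report, decisions = apply_filters(profiles, rrna_ids=["t1"])
        assert decisions[0].verdict == "rrna"
        assert report.n_removed_rrna == 1 and report.n_kept == 0

    def test_clean_set_passes_untouched(self):
        profiles = self._profiles({f"t{i}": [100] * 150 for i in range(4)})
        kept, report, _ = apply_filters(profiles)
        assert report.n_kept == report.n_input == 4
        assert report.n_removed_low == report.n_removed_gap == report.n_removed_rrna == 0

    def test_counts_partition_input(self):
        profiles = self._profiles(
            {"a": [1] * 100, "b": [40] * 99 + [2], "c": [50] * 100, "d": [9] * 100}
        )
        kept, report, _ = apply_filters(profiles, rrna_ids=["d"])
        assert (
            report.n_removed_low + report.n_removed_gap + report.n_removed_rrna + report.n_kept
            == report.n_input
            == 4
        )
        assert report.n_removed_low == 1 and report.n_removed_gap == 1
        assert report.n_removed_rrna == 1 and report.n_kept == 1


class TestChimeraDetection:
    def test_planted_chimeras_always_flagged(self, clean_deep_config, tmp_path):
        """Every planted fusion transcript is removed by the coverage rules,
        and no uniformly covered clean transcript is falsely flagged."""
        result = pipeline.run_synthetic_pipeline(clean_deep_config, tmp_path / "out")
        verdicts = {d.transcript_id: d.verdict for d in result.decisions}
        chim_keys = set(result.bundle.chimera_ids)
        chim_merged = [
            t.merged_id for t in result.merged.transcripts if (t.kmer, t.id) in chim_keys
        ]
        assert chim_merged, "simulation produced no surviving chimeras"
        assert all(verdicts[c] in {"coverage_gap", "low_coverage"} for c in chim_merged)

    def test_no_false_positives_on_uniform_depth_30(self):
        profiles = {
            f"t{i}": CoverageProfile(f"t{i}", np.full(300 + 50 * i, 30)) for i in range(10)
        }
        _, report, _ = apply_filters(profiles)
        assert report.n_removed_gap == 0 and report.n_kept == 10

    def test_no_read_spans_a_chimera_junction(self, clean_deep_config, tmp_path):
        cfg = clean_deep_config
        bundle = generate_truth_transcriptome(cfg)
        simulate_multik_assemblies(bundle, cfg, tmp_path)
        m1, m2, _s, origins = simulate_reads(bundle, cfg, tmp_path)
        k = cfg.kmer_list[0]
        assembly = merge_mod.load_assembly(bundle.k_assembly_files[k], kmer=k)
        targets = {t.merged_id: (t.kmer, t.id) for t in assembly}
        lengths = {t.merged_id: len(t) for t in assembly}
        sam = tmp_path / "aln.sam"
        write_truth_alignments(bundle, targets, lengths, origins, sam)
        import pysam

        by_key = {(t.kmer, t.id): t.merged_id for t in assembly}
        junction_of = {
            by_key[key]: bundle.junctions[key]
            for key in bundle.chimera_ids
            if key in by_key
        }
        assert junction_of, "simulation produced no chimeras at this k"
        n_chimera_reads = 0
        with pysam.AlignmentFile(str(sam), "r") as fh:
            for rec in fh:
                j = junction_of.get(rec.reference_name)
                if j is None:
                    continue
                n_chimera_reads += 1
                # alignment lies entirely on one side of the junction
                assert rec.reference_end <= j or rec.reference_start >= j
        assert n_chimera_reads > 0
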