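"""Header parsing, representative selection, identity and greedy merging."""

import random

import pytest

from multik.errors import ConfigError, DomainError, FormatError, IntegrityError
from multik import fio
from multik.merge import (
    AssembledTranscript,
    cluster_and_merge,
    load_assembly,
    pairwise_identity,
    parse_oases_header,
    select_representatives,
)
from multik.simulate import SimulationConfig, generate_truth_transcriptome, simulate_multik_assemblies

from oracles import greedy_cluster_oracle, identity_oracle


def _tx(locus, seq, kmer=21, conf=0.5, idx=1, count=1):
    return AssembledTranscript(
        kmer=kmer,
        locus_id=str(locus),
        transcript_index=idx,
        isoform_count=count,
        confidence=conf,
        declared_length=len(seq),
        sequence=seq,
    )


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestHeaderParsing:
    def test_full_header(self):
        t = parse_oases_header("Locus_4_Transcript_2/3_Confidence_0.429_Length_812")
        assert (t.locus_id, t.transcript_index, t.isoform_count) == ("4", 2, 3)
        assert t.confidence == pytest.approx(0.429)
        assert t.declared_length == 812

    def test_singleton_isoform(self):
        t = parse_oases_header("Locus_1_Transcript_1/1_Confidence_1.000_Length_100")
        assert t.transcript_index == t.isoform_count == 1

    @pytest.mark.parametrize(
        "header",
        ["Contig_17", "Locus_1_Transcript_1_Confidence_1.0_Length_10", ""],
    )
    def test_dialect_violations_rejected(self, header):
        with pytest.raises(FormatError):
            parse_oases_header(header)

    def test_index_exceeding_isoform_count_rejected(self):
        with pytest.raises(FormatError, match="exceeds"):
            parse_oases_header("Locus_1_Transcript_4/3_Confidence_0.5_Length_10")

    def test_load_checks_declared_length(self, tmp_path):
        p = tmp_path / "a.fasta"
        fio.write_fasta(p, [("Locus_1_Transcript_1/1_Confidence_0.500_Length_150", "A" * 120)])
        with pytest.raises(IntegrityError, match="declares 150"):
            load_assembly(p, kmer=21)

    def test_load_drops_sub_floor_transcripts(self, tmp_path):
        p = tmp_path / "a.fasta"
        fio.write_fasta(
            p,
            [
                ("Locus_1_Transcript_1/1_Confidence_0.500_Length_99", "A" * 99),
                ("Locus_2_Transcript_1/1_Confidence_0.500_Length_100", "C" * 100),
            ],
        )
        loaded = load_assembly(p, kmer=21)
        assert [t.locus_id for t in loaded] == ["2"]


class TestRepresentativeSelection:
    def test_length_dominates_confidence(self):
        a = _tx(1, "A" * 800, conf=0.4, idx=1, count=2)
        b = _tx(1, "C" * 600, conf=0.9, idx=2, count=2)
        assert select_representatives([a, b]) == [a]

    def test_singleton_locus(self):
        a = _tx(3, "A" * 500)
        assert select_representatives([a]) == [a]

    def test_confidence_breaks_length_tie(self):
        a = _tx(1, "A" * 500, conf=0.4, idx=1, count=2)
        b = _tx(1, "C" * 500, conf=0.9, idx=2, count=2)
        assert select_representatives([a, b]) == [b]

    def test_lowest_index_breaks_full_tie(self):
        a = _tx(1, "A" * 500, conf=0.5, idx=2, count=3)
        b = _tx(1, "C" * 500, conf=0.5, idx=1, count=3)
        assert select_representatives([a, b]) == [b]

    def test_one_representative_per_locus(self):
        txs = [_tx(i % 4, "A" * (100 + i), idx=1, count=1) for i in range(12)]
        reps = select_representatives(txs)
        assert sorted(t.locus_id for t in reps) == ["0", "1", "2", "3"]


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        rng = random.Random(0)
        s = _random_seq(rng, 100)
        assert pairwise_identity(s, s) == 1.0

    def test_five_substitutions_in_hundred(self):
        rng = random.Random(1)
        s = _random_seq(rng, 100)
        t = list(s)
        for i in (5, 25, 50, 70, 95):
            t[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[i]]
        assert pairwise_identity(s, "".join(t)) == pytest.approx(0.95)

    def test_disjoint_alphabets_give_zero(self):
        assert pairwise_identity("A" * 50, "C" * 50) == 0.0

    def test_exact_fragment_is_fully_identical(self):
        rng = random.Random(2)
        s = _random_seq(rng, 1000)
        assert pairwise_identity(s, s[300:900]) == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(DomainError):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_on_mutated_fragments(self):
        rng = random.Random(42)
        for _ in range(120):
            parent = _random_seq(rng, rng.randint(40, 110))
            child = list(parent)
            for _ in range(rng.randint(0, len(parent) // 8)):
                i = rng.randrange(len(child))
                op = rng.random()
                if op < 0.6:
                    child[i] = rng.choice("ACGT")
                elif op < 0.8 and len(child) > 30:
                    del child[i]
                else:
                    child.insert(i, rng.choice("ACGT"))
            a = rng.randrange(0, max(1, len(child) // 4))
            b = len(child) - rng.randrange(0, max(1, len(child) // 4))
            child = "".join(child[a:b])
            if not child:
                continue
            assert pairwise_identity(parent, child) == pytest.approx(
                identity_oracle(parent, child)
            )


class TestClusterAndMerge:
    def test_fragment_collapses_into_parent(self):
        rng = random.Random(3)
        s = _random_seq(rng, 1000)
        merged = cluster_and_merge([_tx(1, s, kmer=21), _tx(2, s[200:800], kmer=33)])
        assert len(merged.transcripts) == 1
        assert len(merged.transcripts[0]) == 1000
        assert merged.clusters[0].pairwise_identity_to_rep["33_Locus_2"] == 1.0

    def test_unrelated_sequences_stay_apart(self):
        rng = random.Random(4)
        merged = cluster_and_merge(
            [_tx(1, _random_seq(rng, 500), kmer=21), _tx(2, _random_seq(rng, 500), kmer=25)]
        )
        assert len(merged.transcripts) == 2

    def test_threshold_validation(self):
        with pytest.raises(ConfigError):
            cluster_and_merge([_tx(1, "A" * 100)], identity_threshold=1.5)

    def test_merging_is_idempotent_under_duplication(self):
        rng = random.Random(5)
        reps = [_tx(i, _random_seq(rng, rng.randint(100, 400)), kmer=21) for i in range(8)]
        merged = cluster_and_merge(reps)
        again = cluster_and_merge(
            merged.transcripts + [_tx(99, merged.transcripts[0].sequence, kmer=41)]
        )
        assert sorted(t.sequence for t in again.transcripts) == sorted(
            t.sequence for t in merged.transcripts
        )

    def test_output_nonredundancy_and_rep_dominance(self):
        rng = random.Random(6)
        base = [_random_seq(rng, rng.randint(120, 500)) for _ in range(10)]
        reps = []
        n = 0
        for s in base:
            for _ in range(rng.randint(1, 3)):
                cut = rng.randint(100, len(s))
                start = rng.randint(0, len(s) - cut)
                n += 1
                reps.append(_tx(n, s[start : start + cut], kmer=21))
        merged = cluster_and_merge(reps)
        out = [t.sequence for t in merged.transcripts]
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert pairwise_identity(out[i], out[j]) < 0.95
        by_id = {t.merged_id: t for t in reps}
        for cl in merged.clusters:
            rep_len = len(by_id[cl.representative_id])
            assert all(len(by_id[m]) <= rep_len for m in cl.member_ids)
            assert all(v >= 0.95 or m == cl.representative_id
                       for m, v in cl.pairwise_identity_to_rep.items())

    def test_agrees_with_greedy_oracle(self):
        rng = random.Random(7)
        seqs = []
        parents = [_random_seq(rng, rng.randint(150, 400)) for _ in range(6)]
        while len(seqs) < 40:
            p = rng.choice(parents)
            cut = rng.randint(100, len(p))
            start = rng.randint(0, len(p) - cut)
            frag = list(p[start : start + cut])
            for _ in range(rng.randint(0, 3)):
                i = rng.randrange(len(frag))
                frag[i] = rng.choice("ACGT")
            seqs.append("".join(frag))
        reps = [_tx(i, s) for i, s in enumerate(seqs)]
        merged = cluster_and_merge(reps, prefilter=True)
        oracle = greedy_cluster_oracle(seqs, 0.95, pairwise_identity)
        got = sorted(sorted(cl.member_ids) for cl in merged.clusters)
        want = sorted(sorted(reps[i].merged_id for i in members) for members in oracle)
        assert got == want

    def test_recovers_locus_count_under_full_capture(self, tmp_path):
        cfg = SimulationConfig(
            seed=13,
            n_loci=20,
            kmer_list=(21, 29, 41),
            capture_prob_per_k=1.0,
            truncation_frac_range=(1.0, 1.0),
            chimera_rate=0.0,
            length_range=(100, 800),
        )
        bundle = generate_truth_transcriptome(cfg)
        simulate_multik_assemblies(bundle, cfg, tmp_path)
        reps = []
        for k, path in bundle.k_assembly_files.items():
            reps.extend(select_representatives(load_assembly(path, kmer=k)))
        merged = cluster_and_merge(reps)
        assert len(merged.transcripts) == cfg.n_loci
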