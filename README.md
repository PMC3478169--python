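# multik

Post-processing toolkit for **multi-kmer de novo transcriptome assemblies**
from short paired-end reads, written for projects on non-model organisms
where no reference genome exists and the assembly itself must be quality-
controlled from internal evidence.

A de Bruijn assembler run at a single k-mer size cannot serve a whole
transcriptome: highly expressed transcripts assemble best at high *k*,
rare transcripts at low *k*. The standard remedy is *additive multiple-k*
assembly — assemble at several *k* (here 21–41), then collapse the pooled
output into a non-redundant transcript set. `multik` implements every
bespoke computational stage around that idea:

1. **Read QC** (`multik.readqc`) — trim each read to its longest contiguous
   segment with per-base Phred ≥ 13, drop reads < 25 bp, keep the surviving
   mate of a broken pair as a singleton; report Q20% (reads with mean error
   probability `p = 10^(-Q/10)` below 1%), N% and GC%.
2. **Representative selection & merging** (`multik.merge`) — parse
   Oases-style `Locus_i_Transcript_j/m_Confidence_c_Length_L` headers, keep
   one transcript per locus (longest, then highest confidence), pool all
   *k*, and cluster greedily at ≥ 95% identity keeping the longest
   transcript per cluster. Identity is `identical aligned bases /
   len(shorter sequence)` under a semi-global affine alignment (match +1,
   mismatch −1, gap open −2, extend −1, overhangs of the longer sequence
   free), so a high-*k* fragment is 100% identical to the low-*k*
   transcript containing it.
3. **Coverage validation** (`multik.coverage`) — per-base depth from SAM
   alignments of the reads mapped back to the assembly; remove transcripts
   with mean depth < 3, transcripts containing a base at ≤ 1/10 of their own
   mean depth (the signature of a chimeric join, which few fragments span),
   and rRNA-flagged transcripts.
4. **Feature scans** (`multik.features`) — perfect microsatellites of
   primitive 2–4 bp motifs at ≥ 10/7/5 units (di/tri/tetra, i.e. ≥ 20 bp),
   RepeatMasker `.out` parsing, a repeat-category summary, rRNA flagging.
5. **Annotation merging** (`multik.annotate`) — 12-column BLAST tabular
   input from several reference sets, top hit per query (lowest e-value,
   then highest bitscore), annotated/unannotated calls at e ≤ 1e−5,
   unique-subject counting with a transcriptome-coverage estimate, and a
   six-frame ORF completeness classifier.
6. **Statistics & orchestration** (`multik.stats`, `multik.pipeline`) —
   N50 (largest L with cumulative length of contigs ≥ L covering half the
   assembly), length/coverage histograms, and a consolidated per-stage
   report that asserts `final = merged − coverage-removed − rRNA-removed`.
7. **Synthetic studies** (`multik.simulate`) — a ground-truth generator
   (skewed expression, per-k capture and truncation, planted chimeras and
   microsatellites, per-cycle read qualities) so every stage can be tested
   against a known answer without any download.

## Worked example

Generate a synthetic study (25 loci, 6 k-assemblies, 5,000 read pairs) and
run every stage over it:

```sh
$ multik simulate --seed 3 --n-loci 25 --n-read-pairs 5000 --outdir demo
 ...
      Merged                 34     803     612    5651        20819
      Final                  28    1468     654    5651        18316

read_qc: 10000 reads in, 9953 retained (4953 pairs, 47 singletons), 47 removed
multik_merge: 120 representatives from 6 assemblies -> 34 merged
coverage_qc: 34 in, 6 removed by coverage, 0 removed as rRNA, 28 kept
```

120 per-locus representatives from the six assemblies collapse to 34
non-redundant transcripts (the extra 9 beyond the 25 true loci are
truncated copies below the 95% identity overlap, plus planted chimeras);
the coverage filter then removes 6 transcripts — every planted chimera
among them — leaving a final set of 28.

```sh
$ multik stats demo/final.fasta
n_transcripts  n50   mean_len  max_len  min_len  total_bases  n_over_1kb
28             1468  654       5651     100      18316        3

$ multik scan-msat demo/truth.fasta
3 microsatellites (1 di, 1 tri, 1 tetra) across 3 transcripts
```

The three microsatellites are exactly the ones the generator planted
(`(AC)₁₂`, `(AAG)₈`, `(ACGT)₆`), recovered at their recorded coordinates.

The same stages run on real files: `multik trim`, `multik merge`,
`multik coverage`, `multik repeats`, `multik annotate`, or all together via
`multik run pipeline.yaml`.

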