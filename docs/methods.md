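# Methods

This note records the models, conventions and numerical choices behind
`multik`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and where
the genuinely open design decisions were resolved.

## Read quality model and trimming

Reads carry per-base Phred scores Q with error probability
`p = 10^(-Q/10)`. Trimming keeps the longest contiguous run of bases with
Q ≥ `phred_min` (default 13, i.e. p ≈ 0.05); ties between equal-length runs
break leftmost, which is deterministic and 5′-biased like common trimmers.
Reads shorter than `min_len` (default 25 bp) after trimming are removed;
when exactly one mate of a pair survives it becomes a singleton. Trimming
is idempotent and monotone in the threshold (property-tested).

Q20% counts reads whose *mean* per-base error probability is strictly
below 1% — a read of uniform Q20 bases (mean error exactly 1%) does not
count. GC% is computed over non-N bases; the median length is the lower
median for even counts. Summaries cover retained reads only; reads removed
by the length filter do not enter the post-trimming length statistics.
Only Sanger Phred+33 FASTQ is accepted; files whose quality distribution is
explicable only as Phred+64 (all scores ≥ 31 with some above the Phred+33
Illumina ceiling) are rejected rather than silently mis-scaled.

## Representative selection and additive multiple-k merging

Assembler output headers (`Locus_i_Transcript_j/m_Confidence_c_Length_L`)
are validated against the sequences; transcripts below 100 bp are dropped
on load, matching the usual assembler reporting floor. One representative
per locus is chosen by (1) maximum length, (2) maximum confidence,
(3) lowest isoform index. The precedence of length over confidence is a
design choice: it is the rule consistent with the later cluster rule
("keep the longest member"), though the original per-locus scripts in this
field vary.

Pooled representatives from all k are clustered greedily: visit sequences
longest-first (ties by input order); each joins the *first* existing
cluster whose representative it matches at ≥ `identity_threshold`
(default 0.95), else it founds a new cluster. First-fit, not best-fit,
mirrors the incremental greedy scheme of the standard redundancy-removal
tools and is deterministic. Every cluster representative is its longest
member by construction, and the merged output is exactly the representative
set.

**Identity definition.** Identity is the number of identically aligned
bases divided by the length of the shorter sequence, from a semi-global
alignment in which the shorter sequence is aligned end-to-end and the
longer sequence's overhangs are free (match +1, mismatch −1, gap open −2,
gap extend −1). The shorter-sequence denominator is what makes a high-k
fragment collapse into its full-length low-k parent — the point of
additive multiple-k merging. Because several alignments can share the
maximum score while differing in identical-base count, the identity is
defined as the *maximum identity count among maximum-score alignments*,
computed exactly by a dynamic program over lexicographic
(score, identities) cells. This makes identity a well-defined function of
the sequence pair; a general-purpose aligner that returns an arbitrary
co-optimal alignment does not. The DP kernel is JIT-compiled (numba) with
a pure-numpy fallback; tests verify it against an independently written
loop-based DP and against Biopython's optimal alignment score.

A shared-11-mer prefilter skips alignments between sequences with no
11-mer in common; at a 95% threshold such pairs cannot realistically
cluster, and the greedy result is verified against a prefilter-free
brute-force oracle on small sets.

## Coverage validation

Per-base depth is accumulated from SAM records: CIGAR M/=/X add depth,
D/N consume reference without depth, I/S/H/P consume none. All mapped
records count — no mapping-quality filter, and paired and singleton
mappings contribute identically. Filters, in precedence order
rRNA → low coverage → coverage gap (each transcript counted once):

* **low coverage**: mean depth < 3 (strict, so a 2.9 mean is removed and a
  3.0 mean kept);
* **coverage gap**: any base with depth ≤ mean/10, *inclusive* — "dropped
  to one tenth" is read as attaining the bound; whether the historical
  scripts used < or ≤ is unknowable, and the boundary is covered by tests;
* **rRNA**: membership in a flag list (from a repeat scan or user-supplied).

The gap rule is scale-invariant (multiplying a depth vector by any positive
integer cannot change the verdict — property-tested). By default it applies
to every base including transcript ends; an `end_margin` parameter excludes
the terminal ramp-down of width ~read-length that arises purely because
fewer fragments can start near an end. The synthetic pipeline sets
`end_margin = read_length`; on real data mapped with a local aligner the
default margin 0 reproduces the stricter historical behaviour.

## Microsatellite scanning

Perfect (uninterrupted) tandem repeats of primitive 2–4 bp motifs are
reported when they meet the unit thresholds 10/7/5 for di/tri/tetra motifs,
so every reported locus spans ≥ 20 bp. A motif is primitive if it is not a
whole-number repetition of a shorter motif (a poly-A run is not an "AA"
repeat; `(ACAC)ₙ` is reported once as the dinucleotide). One maximal run
yields one hit, anchored at the leftmost start of the periodic stretch and
spanning a whole number of units, named by its canonical motif — the
lexicographically smallest rotation of the motif or of its reverse
complement. Adjacent runs of distinct motifs are reported separately (no
compound merging), a noted divergence risk against tools that merge
compound repeats. The scanner is verified hit-for-hit against an exhaustive
every-motif-every-start oracle.

## Repeat summaries and annotation merging

RepeatMasker `.out` files (3 header lines, whitespace columns, 1-based
inclusive query coordinates) are parsed as-is; annotations are bucketed
into the conventional category tree (retroelements → SINE/LINE/LTR
subfamilies, DNA transposons, small RNA, satellites, simple repeats, low
complexity; unknown classes → unclassified interspersed repeat). Within a
category, overlapping features on one transcript are merged before
measuring occupied bases, so a base is never counted twice per category;
percentages are of total assembly bases, rounded to 2 decimals. Transcripts
with any `rRNA`-class feature feed the coverage stage's removal list.

BLAST tabular hits are significant at e-value ≤ 1e−5 — inclusive, the
convention of the BLAST tools themselves, although "less than" phrasing is
common in write-ups; a strict mode is available. Top hit per query: lowest
e-value, then highest bitscore, then file order. A transcript is annotated
iff any source yields a significant hit; union counts are bounded by the
per-source counts (property-tested). The transcriptome-coverage estimate is
`100 × unique subjects / reference set size`, e.g. 6,968 unique chicken
UniGene genes out of 31,576 ≈ 22%.

The ORF completeness classifier is this package's own documented analog of
full-length assessment tools (whose internals are not published): the best
ORF over six frames is the longest stop-free codon run, taken from its
first ATG when present and ranked by (completeness, length). `full_length`
requires both start and stop codons and, when a reference hit with known
subject length is supplied, subject coverage ≥ 0.9; coverage in [0.5, 0.9)
gives `putative_full_length`; everything else is `partial`. The 0.9/0.5
thresholds are module constants exposed as parameters.

## Assembly statistics

N50 is the standard contig N50: the largest length L such that contigs of
length ≥ L jointly contain at least half the total bases (verified against
a brute-force cumulative-sum oracle on fuzzed multisets). Mean length is
rounded half-up to an integer to match conventional summary tables. A
100 bp length floor applies everywhere at load. Histograms are left-closed
right-open with a trailing overflow bin, so totals are conserved.

The consolidated pipeline report carries one Initial and one Representative
row per k plus Merged and Final rows, and enforces the identity
`final = merged − coverage-removed − rRNA-removed`.

## The synthetic study generator

The generator emulates, at desk scale, the situation the pipeline was
built for: tens of millions of 50 bp paired reads from one tissue,
assembled at k = 21, 25, 29, 33, 37, 41.

* **Truth transcriptome** — `n_loci` (default 100) random transcripts with
  lognormal lengths (median 450 bp, σ = 0.8, clipped to 100–5,750 bp),
  matching the short-skewed length distribution of real assembled
  transcript sets rather than a uniform draw over the same span.
  Expression follows a discretised power law (rank⁻ˢ, s = 1 by default),
  producing the high/low coverage dichotomy that motivates multiple-k
  assembly. Microsatellites are planted verbatim at recorded coordinates
  with flanking bases forced to break periodicity, so each is a maximal
  repeat the scanner must recover exactly. A fraction (2%) of loci is
  tagged ribosomal.
* **Per-k assemblies** — each locus is captured per k with probability 0.8
  as 1–3 isoforms, each keeping a contiguous substring (50–100% of the
  locus, uniform anchor) under an Oases-style header. Chimeras — the 5′
  half of one locus joined to the 3′ half of another, junction recorded —
  are added at a binomial rate (5%) per assembly.
* **Reads** — fragments sampled ∝ expression × length with normal insert
  size (200 ± 20 bp); mate 2 is the reverse complement of the fragment's 3′
  end. Per-base Phred = linear per-cycle decay (38 − 0.35·cycle) plus a
  per-read offset (σ = 5, giving the realistic tail of whole bad reads that
  trimming removes) plus per-base noise (σ = 3), clipped to [2, 40];
  substitutions are injected at rate 10^(−Q/10). Indels and N bases are not
  simulated.
* **Alignments** — rather than running an external mapper, truth-faithful
  SAM records are written: a read maps to every target whose provenance
  segment fully contains the read's source interval. Reads are drawn from
  chimera *parents*, so no read spans a chimera junction and mapping back
  produces the internal trough the coverage filter detects — by
  construction, as in real data by biology.

All outputs are byte-deterministic given the seed (independent numpy
generator streams per stage, so regenerating one stage never perturbs
another).

**What passing synthetic tests does and does not show.** The generator
covers substitution errors, expression skew, truncation and chimerism, but
not indels, alignment ambiguity from paralogy, strand-specificity artefacts
or coverage biases (GC, hexamer priming). Filter behaviour on real data
near decision boundaries therefore depends on the mapper; the synthetic
results validate the *rules*, not any particular aligner. At the default
desk-scale depth, a noticeable fraction (~10%) of clean but weakly
expressed transcripts trips the gap rule through genuinely spotty coverage
— the same phenomenon that removed ~7% of the merged set in the motivating
study — so the zero-false-positive guarantee is stated, and tested, for
uniformly covered transcripts specifically.

## Problem sizes

Default simulation: 100 loci, 6 k-assemblies, 50,000 read pairs (≈ 60–80×
mean depth); the full pipeline runs in ~10 s on one CPU, and the test
suite's simulations use 20–30 loci with 3 k-assemblies. These sizes were
chosen as the smallest at which every phenomenon of interest (capture
differences across k, redundant truncation clusters, chimera troughs at
≥ 30× flanking depth, sub-threshold expression) occurs robustly.

## Known limitations

* The greedy first-fit clustering is order-dependent by design; it matches
  the historical tool's scheme, not an optimal clustering.
* Compound/interrupted microsatellites are reported as separate perfect
  runs; counts on repeat-dense sequences can differ slightly from tools
  with compound merging.
* The ORF classifier is an analog, not a reimplementation, of published
  full-length assessment software.
* GO annotation and candidate-gene interpretation are out of scope; only
  the counting around them is provided.
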