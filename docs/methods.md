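# Methods

This note records the models, conventions and defaults behind `codon-sda`,
and what the synthetic-data tests do and do not establish.

## Mature tRNA reference

tRNA gene annotations (tRNAscan-SE tabular output or BED12) are normalised
to 0-based half-open coordinates at parse time; tRNAscan's 1-based
inclusive convention, with start > end on the minus strand, is converted by
the parser, and minus-strand genes carry gene-oriented (reverse
complemented) sequences with gene-local intron offsets. The mature
sequence of a gene is its spliced sequence plus exactly one appended 3'
CCA; genes whose genomic sequence already ends in CCA still receive one
appended copy (logged), since the genomically encoded trinucleotide is part
of the gene body, not the post-transcriptional tail. Identical mature
sequences collapse into clusters — the unit all downstream read counting
refers to — so isodecoders with identical mature sequence are deliberately
indistinguishable.

Two artifacts support first-pass read filtering: pre-tRNA records (gene
plus genomic flanks, default 50 nt, clipped and flagged at chromosome
edges) and a genome with every tRNA locus hard-masked to N. The flank
width is a free parameter; 50 nt comfortably covers leader/trailer
sequences of primary Pol-III transcripts.

Mitochondrial and SeC/Sup/Und/iMet genes are parsed and quantifiable but
flagged `is_special` and excluded from the metric-facing supply by default:
the wobble rules below are the cytosolic eukaryotic ones and do not apply
to the mitochondrial decoding system.

## Quantification contract

A read is discarded as non-tRNA or unmature if *any* of its hits lands on a
masked chromosome or overlaps a pre-tRNA flank by at least one base
(half-open interval arithmetic). Among the surviving mature-cluster hits,
the best tier is the set of hits with minimum edit distance (NM); a read
counts for an anticodon iff all its best-tier hits agree on that anticodon,
and is discarded as ambiguous otherwise. This makes the multi-mapping
behaviour of the upstream aligner explicit and testable. Reads with
mismatches are retained — misincorporation at modified positions is a
signal, not an artifact.

RPM uses the assigned-read total as denominator, so every profile sums to
10⁶ and profiles are depth-comparable. Downstream supply uses √RPM;
relative anticodon abundance (RAA) normalises within amino-acid families
defined by each anticodon's cognate codon, excluding anticodons whose
cognate codon is a stop.

## Codon-optimality weights

Decoding weights follow the classical adaptation-index construction over
codon boxes: for a box XY·, the anticodons with A/G/U/C at position 34 are
the reverse complements of XYT/XYC/XYA/XYG, and

    W(XYT) = (1−s1)·t(A34) + (1−s5)·t(G34)
    W(XYC) = (1−s2)·t(G34) + (1−s6)·t(A34)
    W(XYA) = (1−s3)·t(U34) + (1−s7)·t(A34)
    W(XYG) = (1−s4)·t(C34) + (1−s8)·t(U34)

with s = (0, 0, 0, 0, 0.5, 0.5, 0.75, 0.5, 0.5) — the non-optimised
selective constraints; optimising s against expression would presuppose the
codon-optimality it is meant to measure. ATG is decoded by the elongator
Met tRNA alone (no U:G term), so with every anticodon present at equal
abundance ATG necessarily carries half the weight of fully wobble-served
codons. The ninth entry (prokaryotic lysidine C:A decoding of ATA) is
carried in the vector but never applied. Stop codons are excluded,
leaving 61 codons in W. Weights are max-normalised; zero weights are
replaced by the geometric mean of the nonzero weights (the reference
convention for unobserved decoders). `Rw` renormalises to a family maximum
of 1; six-fold amino acids (Leu, Ser, Arg) are single families.

Demand weights `D` apply the same family normalisation to the
expression-weighted codon usage `CU_c = Σ_j c_ij · mRNA_j` (linear-scale
expression, inner join on gene ids). `SDAw = Rw / D` over the 60 codons
excluding Met and stops; zero-demand codons become missing (NaN), never
infinite. Per-gene tAI/RtAI/SDA are geometric means evaluated in log
space; skipped codons (stops, and Met for SDA) are excluded from both the
product and the length. When supply is proportional to demand within
every family, all SDAw equal 1 and every gene scores 1 — the balance limit
the tests verify.

## Misincorporation calling

Only gene-level uniquely mapped reads (exactly one best-tier cluster hit)
enter the pileup, separating modification signal from multi-mapping noise.
A position is called when depth ≥ 20 and the non-reference fraction
≥ 0.1; both thresholds are explicit configuration, chosen so that planted
signals at typical misincorporation fractions (10–50%) are recovered while
isolated sequencing errors at per-base rates ≪ 1% are not. The caller is
a transparent threshold rule by design: the discovery signal is mismatch
frequency, and a full genotyping model adds nothing at these depths.

Sites are projected onto a canonical 76-nt tRNA scaffold (anticodon at
positions 34–36, D-loop 14–21, V-region 44–48, T-loop 54–60) via global
pairwise alignment, so positions on tRNAs with variable-length loops share
one coordinate system. Alignment identity is chance-corrected: the raw
matched-column fraction is rescaled by the 25% agreement expected between
unrelated DNA sequences, so unrelated input scores near 0 rather than near
0.5; sequences below 0.4 corrected identity are labelled `unmapped`.
Positions inside insertions relative to the scaffold get the structural
region name of the last aligned scaffold column (e.g. `V-region`).
Sequencing cannot identify a modification chemically; the output is a
catalogue of candidate positions.

## Cohort statistics

* **Differential:** per feature, two-tailed Wilcoxon rank-sum (exact when
  sample sizes permit and no ties; mid-rank normal approximation
  otherwise); effect size is the log2 ratio of group medians (finite only
  when both are positive); BH correction within one comparison across its
  features.
* **Methylation:** mean beta over [TSS − 1500 nt, gene end], strand-aware
  (upstream is 5' of the gene's strand). Base-resolution bisulfite data
  restrict to the gene body, since Pol-III promoter elements are
  intragenic. Gene values average over positions; isoacceptor values over
  member genes; genes with no covered position are missing and the
  coverage fraction is reported.
* **Copy number:** segment values (log2(CN) − 1 scale) are taken directly
  for fully contained genes and overlap-length-weighted for genes spanning
  breakpoints.
* **MLR:** OLS of √RPM abundance on methylation and CNA per (isoacceptor,
  condition) over complete samples; groups with < 4 complete samples or a
  rank-deficient design are skipped with a flag. Coefficient t-statistic
  p-values are FDR-corrected jointly across all fitted models — the sign
  summary ("are significant methylation effects predominantly negative?")
  is a statement about the whole collection, so the correction must span
  it. The sign test is an exact two-sided binomial test against 0.5.
* **Survival:** the bottom and top `fraction` (default 0.4) of patients by
  score form the low/high groups, ties at the boundary broken by stable
  input order (logged); Kaplan–Meier curves per group and a two-group
  log-rank test. Codon scans restrict to codons whose differential
  direction is consistent in more than 5 conditions net, then correct
  across the scanned codons. Times and censoring indicators are used
  as supplied, with no interval adjustment.

## Synthetic data: what it emulates, what it does not

Generators are driven by one integer-seeded `numpy` Generator per stage;
identical config and seed give byte-identical files, and truth tables are
written beside every dataset.

Toy tRNA genes are scaffold variants — anticodon substitution plus point
substitutions at D-loop/V-region offsets for isodecoders, an 11-nt intron
after position 37 for a configurable fraction of genes, and one
intron-bearing duplicate whose mature sequence matches an existing gene.
Reads are fragments (25–45 nt) drawn multinomially from cluster
abundances; alignment records follow an exact-substring model (every exact
occurrence in the library is a hit; otherwise a single best hit at the
true origin with NM = the mismatch count). Cohort tables come from the
declared linear model, declared multiplicative group shifts, and
exponential survival with a declared hazard ratio.

Consequences worth knowing:

* Because all toy tRNAs share one scaffold, fragments that avoid the
  anticodon and variant positions are cross-anticodon ambiguous and are
  discarded — a deliberately adversarial setting for the ambiguity rules.
  Real tRNA families are more divergent, so real data lose fewer reads.
* A planted modification at an anticodon position can convert a read into
  an exact match for a different isoacceptor; such reads silently migrate
  rather than producing a mismatch signal. This mirrors a genuine
  biological confound of anticodon-loop modifications and is why fixture
  modifications are planted at positions whose altered sequence matches no
  other cluster.
* Passing tests demonstrate the contracts (filtering, assignment,
  recovery, calling thresholds, statistical calibration) — not performance
  on real libraries with adapter artifacts, indels near modified bases, or
  reference bias, none of which the generator emulates.

Default cohort scale follows the study design the toolkit targets: 22
conditions × 64 isoacceptors (1,408 regressions), 50 + 50 samples per
differential comparison, and 200-patient survival cohorts with ~30%
censoring; the acceptance script uses 10⁵ reads for quantification
recovery. These sizes keep the full suite within a few CPU-minutes.

## Numerical choices and edge cases

Geometric means are computed in log space; genes with no scoreable codon
raise. Degenerate differential features (all values identical) get p = 1
and a flag instead of a failure. All-zero abundance or expression vectors
raise; zero-demand codons and uncovered genes propagate as NaN with
tallies. Cluster ids, table rows and site lists are deterministically
ordered, and the pipeline writes a manifest with input checksums so reruns
are verifiable.
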