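# codon-sda

Transfer RNAs are the adaptors of translation: 61 sense codons are read by
~46 anticodon families (isoacceptors) through Watson–Crick and wobble
pairing, and the balance between the cellular *supply* of tRNAs and the
transcriptome's *demand* for their codons shapes how efficiently each
transcript is translated. `codon-sda` is a toolkit for studying that
balance from sequencing data. It is aimed at researchers who want to

* quantify tRNA isoacceptors from small-RNA sequencing alignments,
* detect candidate tRNA modification sites from reverse-transcription
  misincorporation signatures,
* score codons and genes for translational optimality (tAI, relative tAI,
  Supply-to-Demand Adaptation), and
* relate those scores to cohort phenotypes (differential statistics,
  promoter methylation / copy-number regression, survival).

## The statistics at the core

**tAI weights.** For each codon *c* the decoding weight is a wobble-weighted
sum over the anticodons that can read it,

    W_c = Σ_j (1 − s_cj) · tRNA_cj ,

where `tRNA_cj` is the square-root-normalised abundance (√RPM) of
isoacceptor *j* and `s = (0, 0, 0, 0, 0.5, 0.5, 0.75, 0.5, 0.5)` encodes the
pairing penalties (Watson–Crick pairs free; G:U, I:C, I:A, U:G discounted).
The non-optimised s-values are used deliberately: tuning them against
expression data would make "codon optimality" circular. Weights are
max-normalised (`w_c = W_c / max W`), zero weights replaced by the geometric
mean of the nonzero ones, and a gene's tAI is the length-normalised
geometric mean `(∏_k w_{i_k})^{1/l_g}` over its codons.

**Supply-to-Demand Adaptation.** The family-relative supply
`Rw_c = w_c / max_{i∈c_aa} w_i` is compared with the expression-weighted
codon demand `CU_c = Σ_j count(c in gene j) · mRNA_j`, family-normalised to
`D_c = CU_c / max_{i∈c_aa} CU_i`:

    SDAw_c = Rw_c / D_c

defined for the 60 codons excluding methionine and stops. `SDAw > 1` means
the tRNA supply for a codon exceeds the transcriptome's demand. A gene's
SDA is the geometric mean of `SDAw` over its codons.

**Cohort layer.** Differential SDAw/abundance uses two-tailed Wilcoxon
rank-sum tests with Benjamini–Hochberg FDR; per-isoacceptor multiple linear
regression (`abundance ~ β0 + βMe·Me + βCNA·CNA`) relates √RPM abundance to
promoter methylation (mean beta from 1.5 kb upstream of the TSS to the gene
end) and copy number (overlap-weighted segment means), with an exact
binomial test on significant coefficient signs; survival contrasts the
bottom and top 40% of patients by a codon's SDAw with Kaplan–Meier curves
and a log-rank test.

## Worked example

Everything runs on synthetic data with known truth (no downloads):

```sh
codon-sda simulate --seed 1 --out fixtures
codon-sda buildref --genome fixtures/genome.fa --annot fixtures/trnas.txt --out refdir
# -> 41 genes -> 40 clusters
codon-sda quant --sam fixtures/reads.sam --ref refdir --out s1.trna.tsv
# -> assigned=15332 ambiguous=4668 premature=0 unmapped=0
codon-sda metrics --trna s1.trna.tsv --expr fixtures/expression.tsv \
                  --cds fixtures/cds.fa --out s1.weights.tsv
# -> 60 SDA codons, 200 genes scored
codon-sda survival --table fixtures/survival.tsv --out km.tsv
# -> log-rank p = 3.042e-10 (n=80/80)
```

`buildref` collapsed 41 annotated genes into 40 mature clusters because the
fixture contains a duplicated gene pair whose spliced, CCA-tailed sequences
are identical. `quant` counted reads that map unambiguously at the
*isoacceptor* level (reads torn between isodecoders of one anticodon still
count; the 4,668 ambiguous reads spanned different anticodons). The weights
table lists, per codon, `W, w, Rw, CU, D, SDAw`, e.g.

```
codon  amino_acid  W       w      Rw   CU        D       SDAw
TTC    F           366.73  0.849  1.0  14171.72  1.0     1.0
TTT    F           183.36  0.424  0.5  475.75    0.034   14.89
```

here the fixture's Phe-GAA tRNA reads TTC by Watson–Crick pairing and TTT
only through wobble (half the weight), while the simulated transcriptome
rarely uses TTT — so TTT's supply far exceeds its demand (SDAw ≈ 14.9).
The survival fixture plants a hazard ratio of 3 between low- and high-SDAw
patients, which the log-rank test recovers decisively.

An end-to-end YAML-driven run (`codon-sda run --config pipeline.yaml`)
chains the same stages and writes a `manifest.json` with input checksums
and per-stage counts.

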