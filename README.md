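# promoterscan

Multiomic scoring of putative transcription factor binding sites (TFBSs) in
promoter regions.

## The problem

Transcription factors (TFs) bind short DNA motifs (6–24 bp), and a position
weight matrix (PWM) scan of a promoter produces many candidate sites, most of
which are not functional.  Several genome-scale data types carry independent
evidence about which candidates matter: proximity to transcription start
sites (CAGE peaks), co-expression of the TF and the target gene, overlap with
ChIP-Seq binding-event metaclusters, open chromatin (ATAC-Seq), overlapping
expression-affecting variants (eQTLs), local CpG observed/expected ratio, and
evolutionary constraint.  `promoterscan` combines all of these into a single
score per candidate site and ships the evaluation machinery to measure how
much each data type helps.

## The model

A PFM of counts `a_i` over `S` sequences becomes a PWM of log2 likelihood
ratios against a background nucleotide model with pseudocount `b = 0.8`:

    weight(nuc, i) = log2( ((a_i + b/4) / (S + b)) / p_bg(nuc) )

The binding score of a window is the sum of addressed cells; its p-value
comes from the exact null score distribution computed by per-position
convolution under the background model.

Each non-PWM feature contributes a log-likelihood score `LLS = -log2 P(v)`,
where `P(v)` is an empirical tail probability of the observed value `v`
under a genome-wide distribution of that observable — lower tail
`P(x <= d)` for distances (CAGE, ATAC, conservation), upper tail `P(x >= v)`
for metacluster overlap counts, eQTL effect magnitudes, CpG ratios, and
expression-correlation magnitudes.  A floor `eps = 1/(n+1)` keeps every LLS
finite.  The **combined affinity score** of a hit is the exact sum of the
active feature scores:

    human:     PWM + CAGE + correlation + metaclusters + ATAC + eQTL + CpG + conservation
    non-human: PWM + CAGE + CpG + conservation

and is calibrated into an empirical p-value `(r+1)/(n+1)` against the
combined scores of hits on a background promoter corpus.

The benchmark module reproduces the evaluation protocol: 50 bp true-positive
regions centered on verified sites, 50 sampled true negatives per TP (within
a 2,000 bp window, at least 25 bp from the TP center), top-score-per-region
reduction, tie-aware AUROC, the search over all 128 feature combinations
that contain the PWM, paired t-tests between models, and a ChIP-Seq-peak
protocol with TSS-offset-matched true negatives.  A CAGE-like peak caller
derives TSS peaks from RNA-Seq coverage (signal > 5, merge gaps <= 10 nt,
width > 10 nt) for species without CAGE data.

## Worked example

Generate a small synthetic dataset, implant one `TGACGTCA` site 250 bp
upstream of the TSS of transcript `tx_2`, and analyze its promoter:

```bash
promoterscan fixtures -o fixture --seed 12 --genome-length 30000 --n-transcripts 6
echo tx_2 > targets.txt
promoterscan analyze -t targets.txt \
    --fasta fixture/genome.fasta --gtf fixture/transcripts.gtf \
    --jaspar fixture/motifs.jaspar \
    --cage-bed fixture/cage_peaks.bed --metaclusters-bed fixture/metaclusters.bed \
    --atac-bed fixture/atac_peaks.bed --conservation-bed fixture/conserved_elements.bed \
    --eqtl-tsv fixture/eqtls.tsv --correlations-tsv fixture/correlations.tsv \
    --pvalc 0.2 -o out
```

The top row of `out/tx_2.results.csv` (columns abridged) on such a run:

```
tf_name,start,end,strand,sequence,pwm_pvalue,...,combined_affinity,combined_pvalue
TF_A,-250,-242,+,TGACGTCA,1.34e-05,...,782.25,0.031
```

The implanted site is the top-ranked hit: coordinates are TSS-relative
(negative = upstream), `pwm_pvalue` is the PWM-score p-value under the
background model, each `lls_*` column is one feature's bits of evidence,
`combined_affinity` is their sum, and `combined_pvalue` is the empirical
p-value against the background promoter corpus.  An SVG track figure
(`out/tx_2.svg`) shows the scored sites over the conservation, CpG, eQTL,
metacluster, ATAC and CAGE tracks.

Other subcommands: `build-tables` (serialize the empirical score tables as
JSON), `cage-like` (TSS peak calling from bedGraph coverage), `benchmark`
(TP/TN + combination ROC protocol), `fixtures` (synthetic data).

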