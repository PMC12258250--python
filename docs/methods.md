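# Methods

## Scoring model

A candidate TFBS is a PWM hit in a promoter window (default 900 bp upstream
to 100 bp downstream of the TSS; negative values shift the window, with
validation that it stays non-empty).  The PWM cell for nucleotide `nuc` at
position `i` is

    log2( ((a_i + b/4) / (S + b)) / p_bg(nuc) )

with count `a_i`, motif sequence count `S`, and pseudocount `b = 0.8`.  The
background is configurable; the default uses human-genome composition
(A = T = 0.295, C = G = 0.205).  When background nucleotide *counts* are
supplied instead of frequencies, each raw frequency is `(n_nuc + b)/(l_bg + b)`
and the four values are then normalised to sum to one — the pseudocounted
ratios themselves sum to slightly more than one, and a proper probability
vector is required downstream (score-distribution mass, strand symmetry).

Both strands are scanned; windows containing N are skipped.  The null
distribution of window scores under the background model is computed exactly
by per-position convolution of the four cell values, discretised on a lattice
of 1e-3 bits (configurable).  The lattice width is the only approximation:
p-values are exact up to score snapping of at most L/2 lattice steps, which
the tests bound by bracketing against full 4^L enumeration.  A hit's PWM
p-value is the upper tail P(X >= score); the scan retains hits with p-value
<= 0.01 by default.

## Empirical feature scores

Every non-PWM feature maps an observable to bits of evidence through an
empirical tail probability over a genome-wide distribution:

| feature       | observable                              | tail  |
|---------------|-----------------------------------------|-------|
| cage          | distance to each of the gene's peaks    | lower |
| atac          | distance to each in-window peak         | lower |
| conservation  | distance to the nearest element         | lower |
| metaclusters  | count of overlapping metaclusters       | upper |
| eqtl          | \|effect size\| of each overlapping variant | upper |
| cpg           | observed/expected CpG ratio, 200 nt window | upper |
| correlation   | \|Spearman correlation\| of the TF–gene pair | upper |

`LLS(v) = -log2 P(v) >= 0`, with a per-table probability floor
`eps = 1/(n+1)` (n = observations behind the table) so scores beyond the
observed support stay finite.  Distances between intervals are nearest-edge
distances, 0 on overlap, with adjacent half-open intervals at distance 1 —
the same convention the genome-wide per-nucleotide distance vectors use, so
table construction and query are consistent (verified against per-position
brute force).

Two score definitions deserve note:

* The CAGE term sums, over **all** of the gene's peaks,
  `-log2( P(x <= d_i) * p_i / p_total )` where `p_i/p_total` is the peak's
  share of the gene's tag counts.  Placing the share inside the log means a
  low-usage peak contributes *more* bits, which is biologically surprising
  but is the score as defined; a `cage_weighting="inverted"` option instead
  uses the share as an outer multiplier, down-weighting minor peaks.  The
  literal form is the default.
* The ATAC and eQTL terms are likewise sums over all qualifying elements
  (in-window peaks, overlapping variants).  On dense tracks these sums can
  be large in absolute terms; this is harmless for ranking and for empirical
  p-values because the same definition applies to the background corpus.

Missing data never aborts an analysis: a species or gene without a given
track scores 0 for that feature and the result records it in
`absent_features`.  Correlation pairs below the 0.3 magnitude cutoff are
absent from the table and score 0; an optional Bonferroni filter
(corrected p <= 0.05) can additionally gate pair retention when per-pair
p-values are supplied.

## Combined score and calibration

The combined affinity score is the exact sum of the active features — eight
in human mode, four (PWM, CAGE, CpG, conservation) in non-human mode, or an
explicit custom set that always includes the PWM.  Calibration scores a
corpus of background promoters with the same configuration and assigns each
hit the empirical p-value `(r+1)/(n+1)`, `r` = background scores >= the
hit's score.  Background samples are kept **per TF**, not pooled: PWM score
scales differ across motif lengths, and per-TF samples are conservative.
The background corpus is pluggable (real promoter FASTA or the synthetic
generator); the full-genome-scale calibration is reproduced in miniature
with a configurable corpus size (200 promoters of 1,000 bp by default).
Null calibration is checked by self-ranking: each background hit's p-value
against the pooled per-TF sample must be approximately uniform
(KS < 0.1).

## CAGE-like peak calling

For species with RNA-Seq coverage but no CAGE data: (1) keep maximal runs of
coverage with signal strictly > 5; (2) merge runs separated by <= 10 nt;
(3) keep peaks strictly wider than 10 nt.  Merging precedes the width filter
deliberately — a width filter first would delete the sub-peaks the merge
exists to join.  "Within" thresholds are read inclusively (gap <= 10,
TSS distance <= 50); the width/signal thresholds are strict, and boundary
tests pin all four choices.  A merged peak's signal is the maximum over its
members (a sum option exists).  Peaks within 50 nt of an annotated TSS are
associated to every such transcript; unassociated peaks are dropped from the
CAGE-like track.

## Benchmark protocol

True positives are 50 bp regions centered on verified sites (site centers of
odd-width sites round down).  Per TP, 50 true negatives are drawn without
replacement from centers that are simultaneously inside the anchor
transcript's promoter and inside a 2,000 bp window centered on the TP — both
constraints are enforced because both are stated — at least 25 bp from the
TP center, and not overlapping any TP region of the same TF.  TNs may
overlap each other (configurable); infeasible requests fail loudly with the
feasible count.  Every region is scanned at p-value threshold 1 and the top
score represents it; regions with no scorable window carry a -inf sentinel
ranking below all finite scores.  AUROC is the tie-aware rank statistic
(equal to all-pairs counting with ties at one half); it is implemented on
ranks rather than through a ROC-curve library so the -inf sentinel is handled
exactly, and is cross-checked against both the pair-counting oracle and
scikit-learn in the tests.

The combination search caches the eight per-hit component scores once and
recombines them for each of the 128 PWM-containing subsets, so no rescanning
occurs.  "Best overall" maximises mean AUROC across TFs; "best by TF" is the
per-TF argmax; ties break toward the smaller feature set, then feature
order.  Paired t-tests on per-TF AUROCs are two-sided; zero-variance
difference vectors are reported as degenerate with p = 1 rather than raising,
keeping sweeps total.

In ChIP mode, each TF's top 500 peaks by score (ties by genomic order; TFs
under 100 peaks are excluded) give 200 bp TPs centered on peak centers; each
TN applies the identical strand-aware TSS-relative window to a seeded-random
transcript with no peak for that TF.

## Synthetic data

The generator emulates the statistical structure the scores rely on, not
real genome composition: i.i.d. nucleotides at a configurable GC fraction
(default 0.41), evenly spaced transcripts with alternating strands and
1,000 bp promoters, motif implants sampled from a PFM (default an 8-long
motif with 85/5/5/5 columns, about 9 bits — a realistic informative 8-mer,
so implants carry naturalistic variants and classification is imperfect by
design), and tracks whose elements fall within 25 bp of an implant with a
per-feature enrichment probability (default 0.9) and uniformly otherwise.
eQTL magnitudes are |Normal(0,1)|; background correlations are Uniform(-1,1)
filtered at |c| >= 0.3.  Everything is reproducible bit-for-bit under a
fixed seed, and emitted files carry a sidecar JSON of the generating
parameters.

What passing fixture tests do **not** show: real promoters have repeat
structure, isochores, assembly gaps, correlated tracks and tissue-specific
signals, none of which the generator models.  Fixture AUROCs measure
machinery correctness (the full combination must beat the PWM alone when
tracks are enriched at implants), not expected real-data performance.

Default problem sizes — 100 kb fixture genome, 20 transcripts per fixture,
20 TPs x 50 TNs per TF, 200 calibration promoters — were chosen so the whole
suite runs in well under a minute per scenario on one CPU.

## Numerical choices and degenerate inputs

* Score lattice 1e-3 bits; survival function clipped at 1 so p-values stay
  in (0, 1].
* Hit ordering: combined score descending, then plus strand before minus,
  then leftmost start.
* Empty PFM lists return empty results; sequences shorter than a motif warn
  and return nothing; empty element lists fail table construction with the
  feature named.
* Column sums of a PFM may differ by rounding (<= 1 count); larger spreads
  are rejected as not being count matrices.
* Ambiguity codes map to N by default (scanners skip N windows); a strict
  mode rejects them at read time.

## Known limitations

* The Ensembl REST retrieval path is out of scope; all inputs are local
  files in standard text formats.
* Correlation tables are global, not tissue-specific.
* The CAGE literal weighting (share inside the log) is kept for fidelity;
  see above for the inverted alternative.
* BigWig input is not parsed; coverage arrives as bedGraph.
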