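# Methods

This note documents the models and procedures implemented in `permod`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Per-read feature model

A direct RNA read is summarized per aligned base. In RNA002 mode each base
carries 9 features: signal intensity mean (SI, normalized picoamperes),
basecaller modification/error probability (MP, in [0,1]), dwell time at
the base and 10 bases upstream (DT, DT10, in raw-signal samples), and five
trace values — the basecaller's per-base posterior for the reference base
(TR) and for each canonical base (TA, TC, TG, TT). In RNA004 mode, 13
features (SI mean/sd, two dwell times, probabilities of A/C/G/U/stay and
of the reference base, and the three top-ranked model k-mers) are taken at
read offsets −1, 0, +1 around the candidate base, 39 columns in total.
Reads are sense-stranded: bases and 7-mers are always reported in
transcript orientation, and coordinates are 0-based half-open internally
(GFF3 converted on read).

Modification probabilities in alignments use the SAM MM/ML convention for
code `A+a`: ML byte b stands for the probability interval
[b/256, (b+1)/256), decoded to the midpoint (b+0.5)/256, so any
probability round-trips within 1/256.

## Labeling pipeline

Input is a paired design: a treated sample in which the modification is
present at unknown, possibly low stoichiometry s per site, and a control
(knockout-like or IVT) in which it is absent or residual (rate ε ≤ s).

1. **Aggregation and balancing.** Features are pooled per centered 7-mer
   across all reference positions. At each position both samples are
   downsampled without replacement to the smaller count (capped at 1,000
   reads per position per sample), so sample imbalance cannot masquerade
   as signal. Positions missing a sample are dropped and counted.
2. **7-mer selection.** Features are ranked by mean per-7-mer two-sample
   KS statistic; the top two (trace and signal intensity on typical data)
   are tested per 7-mer, with Benjamini–Hochberg correction across 7-mers
   per feature. A 7-mer is selected iff any tested feature has adjusted
   p < α (default 0.01) and D ≥ 0.1. 7-mers with fewer than 30 reads per
   sample are untestable, not "unmodified".
3. **Three-stage labeling** per selected 7-mer, on a stratified 50:50
   train/test split:
   * *Stage 1.* Gradient Boosting (100 trees, depth 3, learning rate 0.1)
     on sample-of-origin labels (control = unmodified, treated =
     modified). Training-half probabilities are **out-of-fold** (5-fold
     CV): resubstitution probabilities of a boosted ensemble concentrate
     at 0/1 and would make every read look confident. Because only the
     treated sample contains modified reads, the score of a truly
     unmodified read plateaus at s/(1+s) rather than 0; the scores are
     therefore min-max calibrated within the 7-mer (2nd/98th percentile)
     before thresholding, which pins the unmodified plateau near 0 and
     the modified population near 1 for any s.
   * *Stage 2.* Calibrated scores inside the confidence band (0.3, 0.7)
     are marked unknown; KNN-kernel label propagation (k = 10, on
     z-scored features, ≤ 1,000 iterations) assigns them from their
     confident neighbours. Confident stage-1 labels are never changed.
     Two guards handle degenerate 7-mers: if the stage-1 scores show no
     control/treated separation at all (one-sided Mann–Whitney
     p ≥ 0.01), the 7-mer carries no evidence of modification and every
     read is labeled unmodified; if one class has fewer than
     max(3, 5% of train) confident seeds, propagation has no anchor and
     the 7-mer collapses to the seeded class. Both are flagged in the
     report.
   * *Stage 3.* A fresh Gradient Boosting classifier trained on the
     relabeled training half predicts every test read; test labels are
     always definite (modified/unmodified), with the predicted
     probability as confidence.

   All stochastic steps derive per-7-mer seeds deterministically from one
   pipeline seed.

The RNA004-style supervised evaluation (fully modified vs. fully
unmodified samples) balances per-position coverage, skips positions below
100 reads and 7-mers with more than one candidate base, splits 50:50 and
reports the test ROC AUC of a 100-tree Random Forest per 7-mer.

## Site calling and thresholds

A read base is modified iff modProb ≥ τ (closed inequality; default 0.5).
A site passes iff coverage ≥ 25 and modified fraction ≥ 5% — at exactly
25× this means at least 2 modified reads. Coverage counts reads carrying a
call at the position; deletions contribute no call and are excluded. The
Youden scan evaluates TPR − FPR on a 0.01-step grid over [0, 1]; ties go
to the smallest τ (conservative toward sensitivity). Replicable sites must
pass with sufficient coverage in *all* replicates. Frequencies are stored
as exact fractions; a pseudocount (0.001) is applied only when exporting
log-scaled plots, never to stored values.

## Co-occurrence (NSD)

For two called sites on one transcript, all quantities are computed on the
C reads spanning both sites — including the per-site modified fractions
f_A, f_B, so that Obs (a read count) and Exp = f_A·f_B·C share one
denominator. NSD = (Obs − Exp)/sqrt(Exp·(1 − f_A·f_B)) is the binomial
z-score of Obs under independence; its null mean is 0 and variance
approaches 1 for large C. Pairs require C ≥ 200 and Exp ≥ 2; only reads
uniquely assigned to one isoform ('unique', 'fsm', 'mono_exon_match')
enter. The distribution-level comparison draws one seeded normal sample of
the same size and standard deviation, recentred to mean exactly 0, and
applies a two-sided Mann–Whitney test; Spearman ρ against log10 pair
distance checks for proximity effects.

## PolyA, exon distance, isoforms

A molecule is m6A-containing iff it has ≥ 1 base with modProb ≥ τ at a
*passed* site; tails shorter than 10 nt are discarded (tail-length
estimators are unreliable below that). Scopes: all reads, reads of genes
with ≥ 1 called site, or per-gene medians.

Exon-boundary distance is min(pos − exon_start, exon_end − 1 − pos) within
the containing exon; the control draws DRACH-motif positions
(D∈{A,G,U}, R∈{A,G}, A, C, H∈{A,C,U}) from the same transcripts,
count-matched and without replacement, and runs through the same distance
code path — only the position source differs.

Isoform-specific stoichiometry keeps genomic sites shared by ≥ 2 isoforms
with ≥ 40× per isoform in every replicate, reports the mean absolute
pairwise frequency difference, tests the most divergent isoform pair with
a two-proportion z-test (BH across sites, per replicate), and flags a site
replicated when the same pair is significant with the same sign in all
replicates. The test choice is not canonical for this problem; it is
labeled in the output.

## Synthetic data

The generators produce the statistical structure the pipeline assumes,
with ground truth retained per read. Distribution families (chosen for
qualitative realism with two parameters each): SI ~ Normal(μ_k, σ) with a
per-7-mer baseline μ_k ~ Normal(80, 5), σ = 4, and an additive shift of
`si_shift_sd` (default 2) standard deviations on modified reads; reference
trace ~ Beta(10, 1.5) unmodified vs. Beta(1.5, 10) modified (high vs.
near-zero), with the remaining trace mass Dirichlet-split over the other
bases; MP ~ Beta(1, 15) vs. Beta(6, 3); dwell ~ LogNormal(log 10, 0.3)
with a ×1.5 factor on the central dwell of modified reads. Treated reads
are modified at rate s per affected site, control reads at ε (default
0.03 — knockout controls are rarely completely devoid of the mark; 0 for
IVT-like controls); unaffected 7-mers are identical across samples.

modProb streams draw from Beta families solved (by bisection at fixed
concentration) to hit the class medians, default 0.0 unmodified / 0.7
modified, then quantized through the 256-bin byte encoding. Site-pair
coupling uses the joint Bernoulli with marginals (f_A, f_B) and Pearson
correlation ρ, i.e. P(1,1) = f_A·f_B + ρ·sqrt(f_A(1−f_A)f_B(1−f_B)),
validated against the Fréchet bounds — exact marginal control with one
dependence parameter. Mixtures draw exactly round(n·target) reads from the
modified pool without replacement and log every sampled ID.

What the generators do **not** emulate: raw current or squiggle-level
noise, basecalling/alignment errors (indels, clipping, multi-mapping),
position-dependent coverage decay, k-mer-dependent effect sizes, or
correlated features within a read beyond the modification indicator.
Passing recovery tests therefore shows the statistical machinery is
correct under the stated model, not that real-data accuracy will match.

## Numerical choices and degenerate inputs

Feature-table rows violating bounds are rejected with line numbers, never
silently. Empty call sets write empty (header-less) bedMethyl files.
Zero-coverage positions are absent from site calls. Ties in feature
ranking break by fixed schema order; ties in the Youden scan by smallest
τ. KS tests use the asymptotic two-sided statistic. Spearman/Mann–Whitney
summaries return None instead of NaN when a side is empty or constant.
Seeds are kept below 2^31; per-7-mer seeds are derived as
(seed·1000003 + crc32(kmer)) mod (2^31 − 1).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
generated at call time: labeling recovery uses 20 affected 7-mers × 1,000
reads (500 per sample), the null selection scan 200 7-mers × 80 reads,
mixture recovery 4,000-read mixtures from 4,500-read pools, and the NSD
calibration 1,000 binomial replicates at C = 10,000. These sizes put
binomial/KS sampling noise well below the tolerances asserted.

## Known limitations

* The labeling accuracy bound holds under strong, well-separated effects;
  with weak effects (≤ 1 SD, no trace shift) per-read accuracy degrades
  gracefully but substantially, as expected from the feature overlap.
* The stage-2 confidence band is a fixed default (0.3, 0.7); extremely
  unbalanced stoichiometries push the calibrated plateau toward the band
  edges and trigger the no-anchor fallback rather than partial labeling.
* Site frequency ignores multi-mapping; unique alignments are assumed.
* The isoform significance test treats reads as independent Bernoulli
  draws, ignoring any read-level covariates shared between isoforms.
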