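# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `duovar`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Read-depth CNV model

The caller treats the read-start count of each sample in a genomic window
as Poisson with a mean proportional to (local copy number / 2) × sample
depth. Copy-number differences between the two samples then appear as
departures of the normalized count ratio from 1.

**Window statistic.** For a window with counts `x` (sample A) and `y`
(sample B), the null hypothesis of equal copy number is tested with the
Geary–Hinkley transform of a ratio of Poisson variables:
`t = (μy·z − μx)/√(μy·z² + μx)` with `z = x/y`, treated as standard normal,
two-sided. The null means are the track's own per-window averages
`μ = Σ(window counts)/n_windows`. With overlapping sliding windows this is
deliberately the sum of *window* counts, not of reads: a read inside the
overlap region contributes to two windows, and only the window-count sum
gives the correct per-window null mean. The log2 ratio
`log2((x/N_A)/(y/N_B))` uses the same totals; its normalization constant
cancels between samples, so the distinction does not affect the ratio.

The transform is a normal approximation. It is accurate in the bulk and
conservative in the far tail at moderate means — at per-window mean 75 the
exact two-sided tail for `x=100, y=50` is 5.7e-5 against a transform
p-value of 1.1e-4 (computed by joint-pmf summation in the test suite). The
property the pipeline relies on is calibration at the decision threshold:
under the null at mean count 30 the measured exceedance of `p ≤ 0.001`
is about 3e-4–5e-4, i.e. the test never over-calls.

**Degenerate counts.** Windows with `x = y = 0` get an undefined ratio,
`p = 1`, and can never be significant. A single zero count keeps the
transform (the `y = 0` limit is `t = √μy`) and reports an infinite-ratio
sentinel.

**Calling rule.** A window is significant when `p ≤ 0.001` *and*
`|log2| ≥ 0.6` (defaults; both configurable). Maximal runs of consecutive
significant windows with a common ratio sign become calls, requiring at
least 10 member windows; mixed-sign runs split at the sign change, and a
single failed window splits a region in two — the known fragmentation
artifact of run-based calling, exercised in the tests. The reported
`combined_p` is the minimum member p-value (the aggregation used by the
summary tables this format imitates is not specified; the minimum is
conservative only in the sense of being reproducible, and is clearly
labelled). The call span runs from the first member window's start to the
last member's end. Sliding windows advance by half the window length, so
runs separated by one non-significant window abut without overlapping.

**Window sizing.** `auto_window_length` finds, by integer bisection, the
smallest window for which an expected-count window at exactly the log2
threshold reaches the p-threshold critical value in both directions, then
multiplies by the configured factor (default 2). At the defaults this puts
the per-window mean near 134 (multiplier 1) / 270 (multiplier 2) — the
regime the detection thresholds are designed for. This is why the recovery
simulations run at mean ≈ 230 per window: at much lower depth (e.g. mean
30) a single two-fold window has p ≈ 0.014 and can never clear `p ≤ 0.001`,
so no run-based caller recovers segments there.

## Synthetic data: what it emulates, and what it does not

* **Read placements** are single-base starts drawn as a Poisson process
  whose rate scales with planted copy number; no fragment-length, GC-bias,
  mappability or mapping-error structure. Depth is the only CNV signal the
  caller uses, so these are exactly the features needed to test it —
  passing tests say nothing about GC or alignment artifacts in real data.
  The recovery simulation plants gains balanced between the two samples;
  a strongly one-sided plant at an unrealistic genome fraction (tens of
  percent) would bias the totals-based normalization, which real data
  (CNV fraction ~0.1%) does not approach.
* **SNP callsets** plant all-or-nothing misses per zygosity class plus an
  allele-drop branch (a missed het emitted as a homozygous call for the
  alternate allele); no base-error or genotype-likelihood model. The array
  table is complete and correct — array error is out of scope.
* **Gene models** are frame-complete multi-exon transcripts (ATG start,
  stop end, no internal stops, introns ≥ 60 bp, GT..AG donors/acceptors)
  packed ≥ 12 kb apart so the 5 kb up/downstream windows of neighbours
  never overlap; planted SNPs record their intended class from the
  generator's own layout/genetic-code bookkeeping, independent of the
  classifier's code path.
* **Orthologue panels** draw each orthologous residue equal to the
  reference with a configurable conservation probability; no phylogenetic
  correlation between species.
* **qPCR tables** use Ct = reference Ct − log2(copy/2)/log2(1+efficiency)
  with i.i.d. Gaussian cycle noise per replicate; copy number 0 censors
  the target Ct entirely.

## SNP filters

The depth filter removes calls strictly deeper than the nearest-rank 95th
percentile of all depths of the same animal ("higher than" read as strict;
including the record itself in the percentile set changes nothing
materially). The uniqueness filter extracts the ±100 bp flank around each
site and keeps the SNP only if that sequence places exactly once in the
reference, counting both strands; the placement counter is a pluggable
predicate so an external aligner can replace the built-in exact substring
search when cross-assembly remapping is wanted. Filters are applied depth
first, then uniqueness.

## Consequence classification and ASC

Classification is per transcript, reduced across overlapping transcripts by
a fixed severity order (essential splice > stop gained > stop lost >
nonsynonymous > splice site > synonymous > 5'UTR > 3'UTR > mature miRNA >
non-coding gene > intronic > upstream > downstream > intergenic). Coding
consequences substitute the (strand-complemented) alternate allele into the
reference codon and translate with the standard genetic code; stop→stop is
reported as synonymous. Splice windows are intronic only: bases 1–2 from
either exon boundary are essential, 3–8 are splice site. The up/downstream
window is 5 kb. A SNP whose stated reference allele disagrees with the
reference base is logged and still classified against the reference codon
(there is no generic "coding" class to fall back to).

ASC uses BLOSUM62 as shipped with Biopython (verified against hand-looked-up
entries in the tests). The score is undefined — not zero — when no
orthologues are available, exactly zero when variant equals reference, and
antisymmetric under swapping reference and variant. ASC histograms use
fixed-width bins (default 3) anchored so that zero is a bin edge; one
orthologue panel per SNP is assumed.

## Concordance accounting

Detectable sites are array genotypes that are not homozygous-reference.
"Called" is position overlap with the sequencing set; "concordant" is
unordered allele-pair plus zygosity equality. The heterozygous discordance
breakdown is denominated over **all** non-concordant detectable het sites
(missed outright or called with a different genotype); "single allele"
means sequencing reported a homozygous genotype for one of the two array
alleles. This matches a generator in which a fraction of het misses
surfaces as homozygous-alternate calls and the remainder vanishes: the
planted allele-drop fraction is recovered as the single-allele share.
Reported percentages are rounded to integers, with full-precision values
kept alongside.

## qPCR copy-number calling

Perfect doubling is assumed in the caller (2^(−ΔΔCt) as printed in the
standard method; amplification efficiency belongs to wet-lab QC, and the
synthetic generator can still inject non-unit efficiency to probe the
mismatch). A censored replicate among valid ones is dropped with a warning;
a fully censored sample is copy number 0; a censored calibrator is an
error. Integer copy numbers come from rounding the continuous estimate
(maximum-likelihood integer calling would need a noise model the Ct tables
do not carry). Mode calibration rescales all relative levels so the modal
rounded level becomes 2 and raises on a tie, listing the tied levels —
there is no principled tie-break. Min/max error ranges come from
per-replicate ΔCt values, paired index-wise when replicate counts match.

## Summaries and enrichment

Per-chromosome CNV summaries include zero rows for CNV-free chromosomes and
a TOTAL row; `aggregate_totals` reproduces the total mean length and
genome fraction from per-chromosome counts alone (the genome median needs
raw call lengths and is only computed from them). Gene overlap is ≥ 1 bp
intersection on half-open intervals, each gene counted once per CNV set.
GO enrichment is a one-sided (over-representation) Fisher exact test per
term against the full annotated gene set supplied as background, corrected
with Benjamini–Yekutieli; the original analysis used a web service's
default background, which is not reproducible, so the background here is
explicit and user-supplied. No GO-graph ancestor propagation is applied.

## Problem sizes in the acceptance script

Null calibration uses 1e5 windows at mean count 30; segment recovery plants
200 two-fold segments of 7 kb (≥ 12 windows at the 1 kb/500 bp tiling) at
mean window count 230; miss-rate recovery uses 200,000 sites; qPCR recovery
is measured over 40 simulated 18-sample assays (720 calls) so the estimated
rate concentrates around its expectation; the classifier and ASC oracles
are exhaustive (all codon substitutions on both strands) and 10,000 random
panels respectively. All randomness derives from the `--seed` argument.

## Known limitations

* The GH p-value degrades below per-window means of ~10; the caller is not
  intended for ultra-low coverage.
* `combined_p` is a minimum, not a combined test; treat it as a flag, not
  an inference.
* The uniqueness oracle is exact substring search — a desk-scale stand-in
  for cross-assembly remapping, not an aligner.
* Classification assumes one transcript model per transcript ID with
  consistent frames; no handling of selenoproteins, non-standard codes or
  splice-region exonic classes.
* The discordance breakdown depends on the denominator convention above;
  analyses that define discordance over called sites only will report
  different shares.
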