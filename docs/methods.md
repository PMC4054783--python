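# Methods

## Scope and data model

The unit of analysis is the **hexamer catalogue**: a named set of unique
6-mers over {A,C,G,T} (`HexamerSet`). Catalogues are strand-naive — ESEs
act on the pre-mRNA sense strand, so no reverse complementation exists
anywhere in the package, and all genomic sequences are supplied
sense-strand by contract (minus-strand genes must be reverse-complemented
upstream).

Coordinates are 0-based half-open internally and 1-based inclusive in
reports. Distances from a splice site count the first exonic (or first
intronic) base as distance 1. Exons are split at their midpoint for all
distance-from-boundary analyses: each position is measured into its own
half from its own boundary.

A position of a sequence is **ESE** with respect to a catalogue iff it is
covered by at least one occurrence of any catalogue motif; all six
positions of a match are flagged, ambiguous bases (N) never match, and the
mask is computed on the human sequence only (the mouse sequence is never
consulted for classification). "Density" is coverage fraction — the
fraction of positions with a True mask — not a match-count rate.

## Catalogue concordance and the true-motif pool

For catalogues drawn independently and uniformly without replacement from
a universe of N motifs, the pairwise overlap is hypergeometric with mean
n₁n₂/N and variance (n₁n₂/N)·((N−n₁)/N)·((N−n₂)/(N−1)); the k-way
intersection has mean N·∏(nᵢ/N), since membership probabilities are
independent across catalogues. Three nulls share one simulation engine
differing only in the universe: all 4,096 hexamers, the pool of motifs
nominated by any screen, or a hypothetical true-ESE pool of a given size.
Observed-vs-null comparisons report the simulated mean and sample SD
(ddof 1), fold O/E, Z = (O−E)/SD, and a one-tailed empirical
P = fraction of replicates ≥ O, reported as the bound "<1/reps" when no
replicate reaches the observation (enrichment is the directional
hypothesis throughout).

The pool-size estimator inverts the k-way expectation: starting from the
analytic seed N₀ = (∏nᵢ/target)^(1/(k−1)), integer bisection on the
simulated expected intersection (strictly decreasing in N) finds the pool
size whose expectation matches the target intersection, rounded to the
nearest 10 — the estimate is only meaningful to that resolution given
Monte Carlo noise (default 3,000 replicates per evaluation, each
evaluation seeded independently from one `SeedSequence`).

Per-catalogue contribution Z-scores compare each catalogue's observed
membership in the ≥k-way intersection with same-sized uniform draws; a
degenerate null SD yields an undefined Z with a warning rather than a
number.

## Positional density

The merged profile layout concatenates the last 100 nt of the upstream
intron, the exon contribution, and the first 100 nt of the downstream
intron. The exon contributes its first and last 50 nt, plus the central
100 nt when longer than 200 nt. For exons of 51–100 nt the two 50-nt
windows overlap; overlapping positions are emitted once (the whole exon is
used), which avoids double counting — the source method leaves this case
unspecified. Masks are computed on the continuous flank+exon+flank
sequence before sampling composite positions, so motifs spanning a
region boundary contribute to every position they cover, each position
assigned to its own region.

Region contrasts: exon-vs-intron and ends-vs-core across exons use
two-sided Mann–Whitney tests (regions may come from different exons); the
matched contrast restricts to exons > 200 nt and pairs each exon's pooled
50-nt flanks against its central 100 nt, with a one-sided Wilcoxon
signed-rank test (flank > core; exact distribution below 25 informative
pairs, normal approximation with continuity correction above) and a
binomial sign test with zero differences dropped. Per-hexamer
normalisation is density divided by catalogue size; because the published
tables are ambiguous between "median density / size" and "median of
per-hexamer densities", both are emitted.

## HPI and codon-usage gradients

A hexamer n₁…n₆ fully specifies four codons (frames 0–3). The observed
codon spectrum of a catalogue sums these frame codons over all motifs,
drops stop triplets and renormalises over the 61 sense codons. The null
redraws `reps` (default 10,000) catalogues of the same size, each random
hexamer the concatenation of two sense codons drawn in proportion to
genomic codon usage, parsed identically (frame-2/3 stop triplets arise
and are dropped exactly as for observed sets). HPI(c) is the Z-score of
the observed proportion against the null mean and sample SD; a zero SD
yields a missing value with a warning. Null catalogues are plain
resamples (duplicates allowed); sampling is inverse-CDF on uniform
draws so that an independent implementation can reproduce the stream
while counting by entirely different code — the dual-implementation test
exploits this. The bundled genome-wide human codon usage table is the
standard per-thousand reference table; any two-column TSV can replace it.

Usage slopes: codons are indexed by codon distance from the boundary
within their exon half (boundary codon = 1), capped at 35 codons
(~100 nt, matching the flank emphasis of the positional analyses).
The response is the codon's share of its synonymous family at that
distance (within-family proportion; absolute share of all sense codons is
available as an option), and the slope is ordinary least squares on the
distance bins where the family occurs.

Concordance over the 87 synonymous pairs orients each pair so the HPI
difference is positive (exact ties dropped and logged); the slope
difference is then expected negative if the catalogue predicts
boundary-directed usage. Two one-tailed tests — an exact binomial on the
sign tally (zero slope differences dropped) and the Spearman correlation
of slope difference on HPI difference (alternative: negative) — are
combined with Fisher's method, χ² = −2(ln P₁ + ln P₂). The overall P is
evaluated at df = 4, the correct reference for two combined tests; a
df = 2 value is also reported because published overall P brackets for
these analyses are consistent with that reference, and the discrepancy is
documented rather than silently matched. P values are floored at 1e-300
before combination.

## Selection tests

Divergence works on codon alignments of orthologous internal exons.
Analysable sites are third positions of aligned codon pairs that are
ungapped in both species, both in a four-fold degenerate family, with the
same family (first two bases) in both — so any third-base difference is
synonymous in both species. Substitution is any base mismatch at that
position; raw proportions are reported with no multiple-hit correction.
Sites are classified ESE/non-ESE by the human mask and tallied by
nucleotide distance from the boundary of their own exon half. SNP
profiles are identical in geometry over all exonic positions, counting a
site once regardless of how many SNP records hit it. Distance cells with
fewer than 50 classified sites in either class are dropped (logged)
before medians over distances and the paired-by-distance two-sided
Wilcoxon test; medians are taken over distances, matching the pairing of
the test (per-exon medians would answer a different question).

PseudoESE control sets redraw each catalogue as `size` distinct hexamers
with bases i.i.d. from the catalogue's average base composition
(duplicates within a set redrawn; default 100 replicates, compared via
the per-distance median). Real-catalogue members are deliberately not
excluded: the contamination is acknowledged and attenuates the pseudo
contrast, making it conservative. The matching is "on average" and
degrades when `size` approaches the number of hexamers attainable from
the composition's support, since uniqueness redraws push the realised
composition toward diversity.

The net-selection estimate chains the in-ESE rate deficit × ESE coverage
near exon ends (rounded to a whole percent, half away from zero) × the
fraction of sequence near exon ends (rounded again). The two-stage
whole-percent rounding is part of the estimate's definition — a 15%
deficit at 30% coverage gives 5% locally and 4% net at 80% coverage of
near-end sequence — so the function reproduces it exactly rather than
carrying full precision.

## Associations

All correlations are Spearman by default (the convention of the
surrounding analyses; a Pearson switch exists for the intron-length
table, whose published "r" is unspecified). Flank density for the
splice-strength analysis uses the terminal 50 nt minus the terminal 3 nt
(those overlap the splice consensus scored by the strength model); class
comparisons use the terminal 100 nt without the 3-nt exclusion. Each exon
end is paired with its own flanking intron and both ends are pooled for
the intron-length correlation, with the <1,501 nt restriction available.
Partial Spearman rank-transforms all variables, residualises response and
predictor on the covariate ranks by least squares with intercept, and
correlates the residuals (t-reference at n−2−k df); collinear covariates
raise an error naming the pair, and residuals that vanish to numerical
noise (e.g. the predictor listed among the covariates) return a partial
correlation of exactly 0. Since ranks are invariant to monotone
transforms, whether intron length enters raw or log-transformed is
immaterial.

Expression summaries mask values below the per-tissue negative-control
mean to zero, drop genes that are zero everywhere after masking,
normalise each tissue by its total signal, and report breadth (fraction
of tissues with nonzero signal), tau = Σ(1 − xᵢ/x_max)/(n−1) (the
standard specificity index: 0 uniform, 1 single-tissue), mean and median.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the package's study conditions: lognormal
exon lengths with median 130 nt (the typical human internal exon) rounded
to whole codons; 100-nt stored intron flanks with lognormal intron
lengths (median 1.5 kb); uniform intronic base composition; exons filled
with codons drawn from genome-wide human usage; a true enhancer pool of
850 hexamers (the package's own capture-recapture estimate of the true
pool size); a logistic embedding curve (plateau 0.06 per start position,
floor 0.01, midpoint 50 nt, scale 10 nt) chosen once to give roughly 30%
enhancer coverage in the 50-nt flanks, the coverage scale reported for
exon ends; divergence rate d = 0.35 at four-fold sites with in-ESE
multiplier r = 0.85 (a 15% deficit); SNP rate s = 0.036 with multiplier
q = 0.833 (0.036 vs 0.030 site proportions); and a Spearman −0.1 between
flank density and splice score (the magnitude scale of the strength
correlations), imposed by Gaussian copula with the Pearson equivalent
2·sin(πρ/6), which preserves the score marginal exactly.

Motif stamping overwrites the background sequence; collisions are
allowed and the truth mask is re-derived from the final sequence as
coverage by pool motifs, so truth equals exactly what the analysis mask
reports for the pool. Optional dials: a constitutive-exon embedding
multiplier (class-comparison tests), a per-pair synonymous gradient that
makes the within-pair codon proportion linear in codon distance (slope
tests), and a copula correlation for intron lengths. Mouse copies
substitute only four-fold third positions (to a uniform different base,
preserving the family); everything else is copied verbatim.

The generator deliberately omits indels, isochore/GC structure, CpG decay,
splice-site consensus sequence, alignment error and ascertainment bias in
SNP discovery. Passing recovery tests therefore establishes that the
estimators are unbiased and correctly calibrated under the generative
model they assume — not that real genomes satisfy that model. Identical
spec and seed give byte-identical outputs; every generator records a
machine-readable truth object and recovery tests read truth only from it.

## Numerical choices and problem sizes

Monte Carlo defaults: 10,000 replicates for overlap simulation and HPI;
3,000 per pool-size evaluation. Wilcoxon tests switch from exact to
normal approximation at 25 informative pairs. Empirical P values are
lower-bounded at 1/reps. The test suite runs its recovery checks at
2,000 exons (divergence and SNP recovery, with 200 bootstrap resamples
over exons for the divergence standard error), 10,000 exons for the
copula check, 100 seeded runs for type-I calibration of the matched
flank/core test and 20 for its power check, and 20 catalogue draws per
pool size for the estimator recovery — sizes chosen so each check's
Monte Carlo error is small against the tolerance it asserts.

## Known limitations

* Exons shorter than 51 nt are excluded from positional profiles by
  construction of the merged layout; the filtering pipeline likewise
  drops frame-trimmed exons shorter than one codon.
* The ortholog filter pairs trimmed exons codon-by-codon and drops
  (with a logged reason) exon pairs whose trimmed spans differ in codon
  count; such pairs need an externally supplied peptide alignment, which
  `backtranslate_alignment` consumes.
* `estimate_pool_size` assumes every catalogue is an unbiased uniform
  sample from one shared pool; heterogeneous ascertainment across screens
  biases the estimate in ways the method cannot detect.
* The HPI null conditions on catalogue size but not on catalogue base
  composition; the pseudoESE machinery, not HPI, is the
  composition-controlled instrument.
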