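# Methods

`songqtl` implements an analysis pipeline for quantitative differences in
*Drosophila melanogaster* male courtship song between an ancestral-range
population (Zambia, ZI) and a derived European population (France, FR):
trait-table construction from replicate song recordings, population
comparison with a family-wise permutation correction, Q_ST/F_ST contrast,
additive QTL mapping over recombinant-inbred-line (RIL) ancestry windows,
residual trait mapping, and a windowed population-genetic outlier screen of
QTL intervals with gene annotation.  This note records the models, the
parameters that matter, the numerical conventions, and what the synthetic
data generators do and do not emulate.

## Trait tables and replicate filtering

A recording is one 30-minute assay of a single male; automated segmentation
reduces it to ~37 quantitative traits (counts/min, durations in s, carrier
frequencies in Hz, transition probabilities and ratios in [0, 1], amplitudes
in arbitrary units) plus two per-recording rates.  Filtering retains a
recording iff it has at least `min_song` = 1 s of song per minute AND at
most `max_sine` = 55 s of total sine song; both comparisons keep boundary
values, because exclusion is defined by strict inequalities ("< 1 s",
"> 55 s").  The 55-s rule is applied to the recording total (its wording
refers to the recording as a unit); the threshold is configurable.  When
averaging replicates into a strain mean, zero trait values are excluded per
trait — a zero is the segmenter's failure code, not a measurement — so one
recording can contribute to some traits and not others.  Missing values
propagate as missing, never as zero.  Trait–trait association uses Pearson
correlation on pairwise-complete strain means, reported with significance
tiers at raw p < 0.05, 1e-3, 1e-6, 1e-9; cells with < 3 complete pairs or a
constant trait are marked not computable.

## Population comparison and family-wise correction

Each trait is compared between the 10 FR and 7 ZI strain panels with a
two-sided Mann–Whitney U test.  The exact two-sided p comes from the null
rank-sum distribution, computed by the classic dynamic-programming
recurrence f(i, j, u) = f(i−1, j, u−j) + f(i, j−1, u) and used whenever the
trait has no ties and both groups are smaller than `exact_cap` = 50;
otherwise the tie-corrected normal approximation with continuity correction
is used (the conventions of R's `wilcox.test`).  The exact table is needed
(rather than a per-test library call) because the permutation engine
evaluates millions of U statistics and maps them to p through one lookup
per trait.

Multiple testing across the trait family is controlled by a min-p
(Westfall–Young style) permutation procedure: per permutation, one shared
relabeling of the 17 strains into pseudo-FR (10) and pseudo-ZI (7) groups is
applied to every trait, the per-trait raw p values are computed, and the
minimum across traits is recorded.  A trait's corrected false-positive rate
is the fraction of permutations whose min-p was at or below that trait's
empirical raw p.  Sharing one relabeling across traits preserves the trait
correlation structure, which is the point of permutation correction here;
independent per-trait shuffling is available (`shared=False`) but provides
no family-wise control.  Corrected FPRs are plain proportions (can be 0); a
(k+1)/(n+1) variant is available by flag.  With 10,000 permutations the
default run is bit-reproducible under a fixed seed.  For small panels the
engine can enumerate all C(n, n1) relabelings exactly (`exhaustive=True`).

## Q_ST vs F_ST

Q_ST is estimated from strain means by a one-way random-effects
decomposition (method of moments, with the standard unbalanced-design
coefficient n0 = (N − Σn_i²/N)/(k−1)); negative between-population variance
components truncate to zero.  Because the strains are fully inbred lines,
the among-line variance within populations is approximately twice the
additive genetic variance, so the default estimator is the inbred form
Q_ST = V_b/(V_b + V_w), which absorbs the conventional factor of two in
V_b/(V_b + 2V_A); the outbred form V_b/(V_b + 2V_w) is available by flag.
The Q_ST value is located within a per-SNP F_ST distribution computed from
haplotype panels hypergeometrically downsampled to the allelic sample sizes
of the phenotyped panel (10 and 7), as the percentile 100·#{F_ST < Q_ST}/N.
Comparing against single-SNP F_ST values (rather than window averages) is
deliberately conservative: it maximizes the variance of the neutral
reference distribution.

## Additive QTL scan

Marker genotypes are FR-ancestry dosages (0/1/2) of genomic windows in 305
RILs derived from 12 generations of FR×ZI intercrossing plus 5 generations
of inbreeding.  Because some genotype classes are rare in many windows, the
scan fits a purely additive model: OLS of the strain-mean trait on dosage,
with LOD = (n/2)·log10(RSS0/RSS1) = −(n/2)·log10(1−R²).  Missing dosages
are dropped pairwise per window (no imputation; panel missingness is low).
Windows with a panel-wide ancestry proportion strictly above 0.90 for
either parent are masked from the scan entirely (a proportion of exactly
0.90 is retained).  Genome-wide significance uses phenotype permutations:
strain means are shuffled across RILs (replicate-level data are not
re-sampled), the full scan is re-run, and the genome-wide maximum LOD
recorded; the threshold is the empirical (1−α) quantile of the maxima at
α = 0.05, taken jointly over all chromosome arms (one threshold per trait).
The genome-wide p of a peak is the fraction of permutation maxima at least
as large.  A QTL's effect size is reported as |2β̂|/|Δ|, the fitted
homozygote-class contrast over the parental strain difference, with the
sign (whether FR ancestry moves the trait toward the FR parent) carried
separately; linked QTLs can inflate these point estimates.

## Peak definition and confidence intervals

Within a chromosome (window adjacency, not arm identity, is the unit of
contiguity — so a region may span the centromere between left and right
arms; per-arm grouping is available), maximal runs of consecutive unmasked
windows at or above the threshold form preliminary peaks.  Two adjacent
peaks merge when the minimum LOD in the valley between them is strictly
greater than the shorter peak's maximum minus 1.5 — a 1.5-LOD support
interval for the shorter peak would already engulf the taller one.  Merging
is applied left-to-right and iterated to a fixed point; masked windows in a
valley carry no LOD and are ignored (an all-masked valley therefore
bridges).  Within a merged region with maximum M, windows with LOD strictly
greater than M − 1.5 "qualify".  The inclusive CI is the contiguous bp span
from the leftmost to the rightmost qualifying window; the restrictive CI is
the set of maximal runs of qualifying windows, possibly noncontiguous — the
sub-intervals most likely to contain the causative locus, and the unit used
by the downstream population-genetic screen.  Ties at the maximum report
the leftmost window as the peak.  A CI boundary abutting masked windows is
extended across the masked stretch: qualifying unmasked windows encountered
beyond it are absorbed and the walk continues; the first non-qualifying
unmasked window stops the walk and is excluded; a stretch reaching the
chromosome end extends the CI to the end with a warning.  Within a run, the
strict reading is used: inclusive CIs do not reach into flanking
sub-threshold windows except through the masked-window extension rule.
One known edge: after extension, bp spans of a region crossing an arm
boundary are reported per constituent arm in BED output.

## Residual trait mapping

For two correlated traits with overlapping QTLs, the trait with the smaller
peak LOD (secondary) is regressed on the trait with the greater peak LOD
(primary) via `scipy.stats.linregress` on complete cases, and the residuals
re-enter the standard scan with a fresh permutation threshold.  A shared
QTL fully mediated by the primary trait disappears from the residual scan;
an independent QTL of the secondary trait survives.  When the two peak
LODs tie, the caller must designate the primary trait explicitly.

## Windowed population-genetic statistics

Per-site F_ST uses the Hudson-form estimator
num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1), den = p1(1−p2)+p2(1−p1),
with sample sizes from non-missing haplotype counts; it is robust to small
and unequal samples, and sites monomorphic for the same allele in both
panels (den = 0) are undefined and excluded.  `fst_fullwin` is the
ratio-of-averages Σnum/Σden over variable sites in the window (stable for
low-frequency sites, unlike averaging per-site ratios); `fst_maxsnp` is the
maximum defined per-site ratio.  Note that a ratio-of-averages can exceed
some per-site ratios, so fst_maxsnp ≥ fst_fullwin is not an identity to be
assumed; what holds exactly is fst_maxsnp = max of per-site values.

Comparative haplotype identity (chi_MD) contrasts mean pairwise
identical-tract lengths between populations.  For each haplotype pair
within a population, maximal runs of identical compared sites are summed in
bp: a run of two or more sites spans from its first to its last site; a
single-site run gets the span between the midpoints of its flanking
inter-site gaps (window edges at the boundaries).  Sites missing in either
haplotype are skipped without breaking runs; pairs with more than 50% of
window sites missing are dropped from the mean (configurable).  chi_MD is
the ratio of the putatively selected population's mean identity to the
reference population's (orientation configurable); a zero reference
identity yields +inf with a flag, and chi_MD(1,2)·chi_MD(2,1) = 1 when both
are finite.  This functional form is a reimplementation from the
description above — the original publication's exact normalization (max vs
summed identity, per-pair vs per-population) could not be verified — and
the single-site midpoint-span rule is what makes the statistic behave
sensibly in sparse-site windows.

Outlier calling ranks each statistic per chromosome arm: a window is
flagged for a statistic when its value reaches the empirical (1−q) quantile
on the arm (q = 0.01), and is an outlier window if flagged for any of the
three statistics.  Quantiles are arm-wide, not restricted to QTL windows.
Degenerate ties (all values equal) flag every window; +inf chi_MD values
rank above all finite ones.  Fewer than ~100 windows per arm triggers a
coarse-quantile warning.

## Gene annotation

GFF3 gene models (1-based closed) are normalized internally to 0-based
half-open; exons are flagged coding when they overlap a CDS of the same
gene.  A gene links to a window if a qualifying exon overlaps it, or if one
of its qualifying exons is the nearest exon strictly to the left or right
of the window boundaries (minimal bp gap; ties link all tied genes; a gene
may be linked both by overlap and as a flanking neighbor, with distinct
link types).  General QTL-interval annotation uses any exon (coding or
noncoding); differentiation-outlier windows use coding exons only.  Strand
is carried but ignored.  Curated candidate lists (e.g. male mating
behavior, wing disc development, nervous system) are supplied as
one-id-per-line files; unknown ids are warned about and ignored.

## Synthetic data: what is emulated

All generators are pure functions of (config, seed).

* **RIL ancestry panels** use a Markov/Poisson tract approximation rather
  than explicit pedigree simulation: breakpoints per arm are Poisson with
  rate (recombination rate) × (intercross generations) × (arm length) —
  2 cM/Mb × 12 generations × 24 Mb ≈ 5.8 breakpoints, i.e. megabase-scale
  tracts — with alternating parental ancestry and per-tract residual
  heterozygosity 0.5^5 ≈ 3% after five inbreeding generations.  Windows
  take the dosage of the tract at their midpoint.  Default 305 RILs × 500
  windows (5 arms × 100).
* **RIL traits** plant additive QTLs with homozygote contrast
  2β = effect_fraction × |parental difference| on the slow-pulse-fraction
  scale (parental means 0.745 vs 0.833, so Δ = −0.088), strain-level noise
  SD 0.03 and replicate noise SD 0.10 with ~19 replicates per RIL — chosen
  to match the within-population strain SDs (0.067–0.125) observed for this
  trait family and the study's replicate counts.  A heavy-tailed (t5)
  replicate-noise option exists because permutation procedures are meant to
  be robust to skewed trait distributions.
* **Population panels** draw 10 + 7 strain means from a multivariate normal
  with block-exchangeable trait correlation (blocks of 5, ρ = 0.6 — traits
  from a common song component are strongly correlated, across components
  nearly independent), between-strain SD 1, and a per-trait FR−ZI shift δ
  split ±δ/2; δ = 0 is the exchangeable null used for calibration.  A
  non-positive-definite user-supplied correlation is repaired by eigenvalue
  clipping with a warning.
* **Haplotype panels** follow the Balding–Nichols model: ancestral
  frequency uniform on (0.05, 0.95), population frequencies Beta-distributed
  around it with divergence parameter F (default 0.2, a plausible
  Africa/Europe scale for differentiated loci); 20 + 20 haplotypes over
  200 × 5-kb windows with ~40 SNPs each (the study's 197 + 96 genomes and
  2,500-SNP windows, scaled down).  An optional sweep replaces population
  1's haplotypes in one window by copies of a template with per-site copy
  fidelity 0.98.
* **Gene models** are non-overlapping, 1–10 exons each, with at least one
  coding exon and planted candidate-list memberships.

Not emulated: audio and segmentation, assay-day and female-response
effects, linkage disequilibrium within windows, inversions, X-specific
dosage, selection on standing variation (sweeps are imposed, not evolved).
Passing recovery tests therefore demonstrates correctness of the estimators
and procedures under the assumed statistical structure, not robustness to
every feature of real song or genomic data.

## Verification experiments and problem sizes

The acceptance suite (also recomputed by `scripts/acceptance.py`) runs:
exact-MW-vs-enumeration for all group sizes ≤ 5; the LOD scan against
independent matrix-algebra OLS (50 × 30, agreement to 1e-10); six
hand-traced peak/CI landscapes; null calibration of both permutation
procedures over 200 replicate datasets each (10 vs 7 × 37 correlated
traits with 500 permutations; 305 RILs × 500 windows with 500
permutations), with rejection rates required inside the binomial 95% band
around 0.05; parameter recovery over 100 simulations of a planted QTL with
effect fraction 0.42 (detection ≥ 90%, inclusive-CI coverage ≥ 80%, mean
effect within 10%); residual mapping over 100 simulations (mediated-QTL
removal and independent-QTL retention ≥ 90%); and popgen consistency
(mean window F_ST within 0.02 of F = 0.2 over 200 windows; swept window in
the top 1% of chi_MD on its arm in ≥ 80% of 100 replicates).  These sizes
keep the full suite under a minute of CPU while leaving the binomial
Monte-Carlo error small relative to each tolerance.

## Known limitations

* The family-wise FPR is a plain proportion over sampled permutations;
  with n_perm permutations its resolution is 1/n_perm.
* chi_MD is quadratic in haplotype count per window; `max_pairs` subsamples
  pairs (seeded) for very large panels.
* Effect sizes at a scanned peak are mildly inflated by selection of the
  maximum-LOD window and by linkage among QTLs; the recovery experiment
  measures the estimate at the detected peak, which is why its mean
  (≈ 0.43) sits slightly above the planted 0.42.
* The reproduction of the study's own summary numbers (filter survivor
  counts 810/5,532, MW p-values 0.0068/0.0185, Table-1 means) requires the
  article's supplementary replicate table, which is not redistributable;
  the corresponding test documents the expected file location and layout
  and fails informatively when the file is absent.
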