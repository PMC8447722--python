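# Methods

`popcnv` analyses within-population genome-size variation driven by large,
independently segregating genomic elements (ISEs), as observed in cyclical
parthenogens such as *Brachionus* rotifers: clones share a basal diploid
genome and differ by 0–6 copies of megabase-scale, satellite-rich elements,
so nuclear DNA content (2C) varies additively. The package detects the
corresponding copy-number-variable regions (CNVs) from short-read depth of
coverage across many libraries, characterises their GC and repeat makeup,
and validates locus copy numbers with droplet digital PCR (ddPCR).

## Coverage model and normalization

The assembly is tiled into fixed windows (default 5 kbp; 50 kbp supported),
coordinates 0-based half-open; terminal partial windows are kept by default
(`drop_partial` exposes the alternative). Per-window mean per-base depth of
coverage (DOC) is normalized by **half** the library's mean exon coverage.
Exons are the most copy-number-stable sequence class, so diploid regions
score 2 and a window's normalized value reads directly as a copy number
against an unphased, collapsed reference in which each element appears
once. "Mean exon coverage" is length-weighted (total aligned bases over
exonic positions divided by total exonic bases), which is robust to tiny
exons.

Cross-library variability is the per-window sample standard deviation
(n−1) of normalized DOC over all libraries (not collapsed to clones).
Windows are classified lowSD (sd ≤ 0.7), interSD (0.7 < sd ≤ 2.0) and
highSD (sd > 2.0); boundary points are assigned to the lower class, a
choice this package fixes because strict inequalities would leave them
unassigned.

Per-class mean coverage is correlated with flow-cytometry 2C genome size by
partial Pearson correlation. The covariate defaults to library-prep batch —
the dominant technical confound, since preparation chemistry inflates
coverage specifically at GC-rich CNV regions — dummy-coded and removed by
residual regression; the test uses df = n − 2 − q.

## CNV detection

Detection merges adjacent 5-kbp windows per contig:

1. **Seed**: cross-library SD > 0.7 (an empirically determined threshold
   for exon-normalized data; configurable).
2. **Merge**: adjacent seed windows join one CNV iff their per-library
   coverage vectors are significantly correlated at p < 0.05. The default
   correlation is partial Pearson with prep batch partialled out; plain
   Pearson is available. p-values come from the t-transform of r; no
   multiple-testing correction is applied by default (a Benjamini–Hochberg
   switch exists).
3. **Contig ends**: the very first and last window of a contig often show
   deviant coverage; they are folded into an adjacent CNV when their
   neighbor belongs to one. A deviant edge window next to diploid sequence
   is *not* used to seed a CNV — the rule exists to avoid spurious
   breakpoints at contig ends.
4. **Bridging**: two CNVs separated by exactly one window (a "stopping
   breakpoint") merge iff the two windows flanking the gap are
   significantly correlated; this pass iterates to a fixpoint and is
   order-independent for one-window gaps.
5. **Length filter**: runs shorter than 3 windows are discarded, last.

Windows with numerically zero variance (e.g. noise-free diploid rows) have
undefined correlations and are treated as not significant. Detection is
fully deterministic. Raising the SD threshold cannot increase total CNV
length on realistic inputs; pathological alternations of correlated and
uncorrelated seeds can in principle break this monotonicity, which is why
the property is checked on simulator-style fixtures rather than claimed
universally.

Summaries report CNV count, total bp, assembly fraction, and an N50 (the
length L such that CNVs of length ≥ L hold at least half of total CNV bp).
Contigs whose length is ≥ 90% (resp. 95%) covered by CNVs are flagged
B-contigs (B90/B95), in analogy to B-chromosomes. Placement distinguishes
whole-contig, contig-edge and internal CNVs.

## GC-content mixture

Per-read %GC is 100·(G+C)/(A+C+G+T), ambiguous bases excluded from both
counts. A 3-component univariate normal mixture is fitted by EM on raw
values (binned fitting is unnecessary at desk scale). Initialization is
quantile-based — component means at the (2i+1)/(2k) sample quantiles, equal
weights, pooled SD — with optional random restarts; convergence is a
relative log-likelihood improvement below 1e−6, capped at 1000 iterations;
component variances are floored at 1e−6 to prevent collapse. The
log-likelihood trace is recorded and is non-decreasing by the EM ascent
property (asserted in tests). Reported components are always sorted by
mean, which makes the report label-switching safe.

Comparing libraries defaults to *fixed-components* mode: component means
and SDs come from one pooled fit and only the weights are re-estimated per
library, so "the low/mid/high fraction" means the same thing in every
library. Full per-library refits are available.

## Repeats and genes

RepeatMasker `.out` hits are converted to 0-based half-open intervals.
Per-family contributions union-merge overlapping hits of the same family
before summing covered bp ("total length covered" is a coverage, not a sum
of hit lengths); cross-family overlaps count once per family. The
enrichment index of family f in region R is
E = (contribution in R / genome-wide contribution) / (|R| / assembly bp);
E > 1 means enrichment. Two identities follow and are tested: the whole
assembly gives E = 1 for every family, and the region-size-weighted mean of
E over any partition of the assembly is exactly 1.

Gene–CNV statistics use Monte Carlo permutation tests (default 1000
permutations) with the plus-one-corrected empirical p-value, which is never
0. Gene membership in a region set uses the gene midpoint by default (an
overlap-fraction rule is available). The density test re-places each gene
uniformly at random in the assembly, preserving its length and staying
within one contig (contigs weighted by admissible start positions); the
duplication-enrichment test permutes duplication labels over all genes with
CNV membership held fixed. Both one- and two-sided alternatives are
exposed, and every report states the permutation scheme, since different
schemes answer subtly different questions.

Because the test statistics are counts, the permutation p-value is slightly
conservative when the null distribution has heavy ties; calibration checks
therefore use gene sets large enough (hundreds of genes) that the tie mass
at the critical value is small.

## ddPCR copy number and coverage conversions

With target amplicon concentration T and two diploid reference amplicons
R1, R2 (N_R = 2 copies per genome),

    CN = T / ((R1 + R2) / 2) · N_R.

The 95% CI is propagated conservatively by taking the extremes of this
ratio over the box of the three concentration CIs; a first-order
delta-method variant is available. Estimates are not rounded by default; a
rounding helper reports the nearest integer and its distance.

Utility conversions: per-base coverage from kmer coverage,
C = C_K·R/(R−K+1) for read length R and kmer size K, and the naïve
coverage estimate total library bp / 1C genome size.

## The simulator

`popcnv.simulate` generates every input the analysis consumes, at the
study's design point: 15 clones sequenced as up to 29 libraries across six
prep batches (A–F), a basal 2C of 414 Mb (207 Mb core haploid), and three
segregating elements (34, 20 and 12 Mb; up to 6/4/3 copies), giving 2C
values spanning roughly 414–730 Mb. The first simulated clone carries zero
copies of everything, anchoring the population at the basal genome size.
Specifics:

- **Transmission.** Each element copy transmits independently with
  probability 1/2, so offspring of a cross are Binomial(c_a, ½) +
  Binomial(c_b, ½) — the simplest model that reproduces independent
  segregation and midparent offspring means.
- **Coverage.** Expected raw DOC of a diploid window equals the library's
  exon mean; an element window with c copies gets (c/2)·exon_mean. Noise is
  multiplicative Gamma with mean 1 (read-depth overdispersion is
  multiplicative and positive); dispersion defaults to 0.1. A per-batch GC
  bias multiplier (1.00–1.15 across batches A–F) applies to windows whose
  GC exceeds 32%, reproducing batch-wise coverage elevation at GC-rich CNV
  regions without modeling fragmentation chemistry.
- **GC reads.** Reads are drawn from the 3-component mixture
  (26 ± 6, 36 ± 2.5, 48 ± 3 %GC), clipped to [0, 100]. Component weights
  derive from genome composition: the basal genome contributes
  (0.70, 0.25, 0.05) of its mass to the low/mid/high components (the
  mid/high entries are the floors reached by zero-element clones), and
  element mass contributes (0, 0.45, 0.55) — elements are satellite
  mixtures with elevated GC, not GC-pure sequence. Consequently the
  low-GC fraction falls, and both elevated fractions rise, with genome
  size, for any population composition.
- **ddPCR.** Template molecules partition into ~15,000 droplets as Poisson
  counts (default 0.1 genome equivalents per droplet, 0.85 nl droplets);
  concentrations are recovered as −ln(fraction negative)/volume with
  binomial 95% CIs. References correspond to 2 copies, the target to the
  true copy number.

Everything is seed-deterministic: the same config and seed give
byte-identical outputs.

**What the simulator does not emulate:** alignment artifacts (mappability,
multi-mapping within satellite arrays), nucleotide-level reads, GC-bias
curves that vary smoothly with GC rather than by threshold, FCM measurement
error, or reference incompleteness (elements absent from the reference are
invisible to read-depth analysis by construction). Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to real-data mapping pathologies. Window
coordinates of simulated elements align to window boundaries, so breakpoint
recovery in tests is only meaningful to ±1 window.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at desk scale: coverage
matrices of a few hundred 5-kbp windows × 29 libraries with elements of 3–200
windows (the study-scale 273-Mb configuration in `default_config()` simulates
in under a second and is used where only genotypes matter, e.g. GC-fraction
correlations); EM recovery uses 20 seeded draws of 100,000 reads; permutation
calibration uses 1000 replicates of 199-permutation tests with uniformity
checked over 200 replicates; ddPCR round-trips use 1000 replicates at 15,000
droplets. Correlation p-values use exact t-distributions, not permutations.
Detector brute-force equivalence is verified exhaustively on single-contig
fixtures of up to 50 windows against an independent, literal re-statement of
the merge criteria.

## Known limitations

- The detector's correlation criterion assumes enough libraries (≈ 10+) for
  the t-test to have power; with very few libraries adjacent variable
  windows can fail to merge.
- The B-contig fraction is computed from called CNV bp, so it inherits the
  ±1-window breakpoint resolution.
- The enrichment index is undefined (NaN, with a warning) for families with
  zero genome-wide contribution, and the partition identity only holds when
  all contributions use the same union-merge overlap policy.
- Real window counts per class depend on assembly filtering conventions
  (partial windows, short contigs) that differ between pipelines; both
  keep-partial and drop-partial behaviors are exposed.
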