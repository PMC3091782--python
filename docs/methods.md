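# Methods

## The problem being modelled

Two populations (a "high" and a "low" line, e.g. divergently selected for
a quantitative trait over tens of generations) are compared with two
assays: individual genotyping of a chip panel (20 individuals per line),
and a single low-coverage sequencing run of one pooled DNA sample per
line (7 males + 4 females each, mean depths 5.19X and 5.53X). The package
asks two questions of this design:

1. **Sensitivity** — what fraction of truly variable sites does a ≥3
   non-reference-read threshold recover from a ~5X pool, as a function of
   the non-reference allele frequency in the pooled population?
2. **Informativity prediction** — how well does the Flanking SNPs Value
   (FSV), computed purely from pooled resequencing, predict the
   between-line allele-frequency difference Δp measured on the chip?

## Synthetic-data generator

No real data accompany this analysis, so the generator is a first-class,
tested component; its defaults *are* the study conditions.

**True SNP landscape.** Per chromosome, SNP positions follow a
homogeneous point process at `snp_density` (default 5 SNPs/kb, a typical
density for comparisons between chicken lines). The chromosome is
partitioned into divergence blocks with i.i.d. exponential lengths (mean
`block_length_mean`, default 30 kb, truncated at the chromosome end; a
chromosome shorter than one average block is rejected). Each block draws
one ancestral frequency p0 ~ Beta(`ancestral_freq_law`) (default
Uniform(0, 1)) and one per-line frequency from the Balding–Nichols law
Beta(p0(1−F)/F, (1−p0)(1−F)/F) with F = `fst_within_block`. Every SNP in
the block receives the block-level line frequency plus a small Beta
jitter (concentration `snp_jitter_concentration`, default 200, i.e. a
standard deviation of ~0.035 at p = 0.5). Neighbouring SNPs therefore
have correlated Δp with an exponentially decaying correlation profile —
the haplotype-block-like structure a flanking-window statistic assumes.
At F = 0 the two lines are exactly identical (no jitter is applied), so
the zero-divergence limit is exact.

Default F = 0.4: lines kept separate under strong divergent selection
for ~40 generations are substantially differentiated, with many SNPs
near fixation for alternative alleles; 0.4 produces a realistic mixture
of low- and high-Δp SNPs, including fixed differences. The block length
is a genuinely free parameter of the design (the real populations' LD
block size is unknown); 30 kb places the optimum window size for FSV
inside the scanned 2–128 kb grid rather than at its edge.

**Chip.** A uniformly random fraction `chip_fraction` (default 0.012 ≈
0.06 chip SNPs/kb, the genome-wide density of a 60 K panel on a ~1 Gb
genome) of true SNPs is placed on the panel. Dosages are
Binomial(2, p_line) per individual; each call is missing with
probability `missing_rate` (default 0.01, consistent with ~97% of SNPs
passing a 0.95 call-frequency filter).

**Pools.** Per line and site, the pool's allele frequency is resampled
as Binomial(22, p_line)/22 — a *finite* pool of 11 diploids, so pool
composition noise is part of the model, as it is in the real design.
Depth is Poisson(`mean_depth_line`); non-reference reads are
Binomial(depth, q(1−e)+(1−q)e) with per-read error e = `seq_error_rate`
(default 0.002). Pileups are emitted at true SNP sites only
(candidate-site model): false positive calls arising from sequencing
error at monomorphic sites are not modelled, nor are mappability, GC or
read-level artefacts — the emulated technology is described only at the
read-count level. Pool individuals are drawn independently per site
(no within-pool linkage), which is adequate because all downstream
statistics are single-site or averages over sites.

Determinism: all three stages derive independent `numpy` streams from
the single `rng_seed` via `SeedSequence`, so one seed reproduces every
output table byte-for-byte.

## Pool caller

A site is a SNP in a line iff that line's pool has ≥ `threshold`
(default 3) non-reference reads; the threshold applies to each pool
independently, so detection in one line never depends on the other
line's reads. Detected lines get S = ref/(ref+nonref); undetected lines
of a detected SNP get S = 1 — the fixation-for-reference assumption,
applied exactly once, here. Sites with no reference read in either line
are flagged `excluded` (their scores carry no between-line information)
but are still counted in the variation-class tally, which partitions
every detected SNP into: both lines all-non-reference / one line
all-non-reference / one line biallelic / both lines biallelic. When one
line is all-non-reference and the other is biallelic the site is
classified by the biallelic line (the classes are applied in the order
above), keeping the four classes an exact partition.

## Chip summaries

Per-line frequencies are dosage sums over non-missing calls; the call
frequency is joint over both lines (one filter, default > 0.95). A SNP
is *polymorphic* when its non-missing dosages are not all identical and
homozygous — note this makes a SNP fixed for the non-reference allele in
both lines non-polymorphic (it shows no variation within or between the
lines, which is the variation the chip filter is meant to capture),
even though it differs from the reference. Such SNPs are excluded from
the sensitivity and correlation analyses along with
reference-monomorphic ones. Frequency binning for the sensitivity
analysis treats each line as one observation per SNP, binned by that
line's own frequency (deciles, top bin right-closed).

## FSV

See the README for the definition. Implementation decisions, where the
definition itself is silent:

- "a total flanking region of W kb" = one window of total width W
  centred on the focal SNP, W/2 per side, closed at both ends;
- the focal SNP's own scores never enter the sums;
- a SNP detected in both lines contributes one term to each sum;
- windows overhanging a chromosome end are truncated (logged), but the
  density filter always uses the nominal W — a truncated window must
  still earn > 1 flanking SNP per kb of *nominal* window per line;
- undefined FSV (either N = 0) and density-filter failure are distinct
  flags; correlation tests use rows passing both.

`fsv_scan` computes all (focal, window) pairs with per-chromosome prefix
sums over the sorted call table; its output is contractually identical
to the direct evaluation `compute_fsv`, and the test suite enforces
equality to 1e−12 on randomized instances.

## Evaluation layer

- **Sensitivity**: redetection fraction of usable polymorphic chip SNPs
  per frequency decile, per line and pooled. Its analytic companion
  `detection_power(λ, q, k, e)` uses Poisson thinning: the
  non-reference read count is marginally Poisson(λq′) with
  q′ = q(1−e)+(1−q)e, so power = P(Poisson(λq′) ≥ k).
- **Δp-stratified FSV means**: mean ± SE of FSV per Δp decile, for one
  window size.
- **Correlation scan**: Pearson product-moment r (two-sided p from the
  t transform, no multiple-testing correction) between FSV and Δp per
  chromosome size class (macro/intermediate/micro via the class map,
  plus "all") and per window, over rows with Δp strictly above the 0.4
  cut (both the filtered and unfiltered variants are available via
  `delta_min=None`); the per-class argmax window is flagged. Strata
  with < 3 rows or zero variance are reported as undefined, not
  dropped.

The focal set for the scan is the usable polymorphic chip SNPs — the
positions whose informativity the statistic is meant to predict.

## Problem sizes and what the tests show

The shared test simulation uses a 20 Mb genome (two 5 Mb macro-, two
3 Mb intermediate, two 2 Mb microchromosomes) — large enough for
~100,000 true SNPs, ~1,200 chip SNPs and a stable correlation scan,
small enough that the full pipeline runs in a few seconds. Passing
tests demonstrate internal correctness (oracle equivalence, bounds,
partitions, determinism) and qualitative recovery of the expected
structure (monotone sensitivity in frequency, FSV–Δp correlation
strongest for high-Δp SNPs, interior optimum window near the block
scale). They do *not* certify performance on real pooled sequencing
data, whose error processes (alignment artefacts, unequal pooling,
reference bias, chip ascertainment) the generator deliberately omits.

## Known limitations

- Biallelic sites only; multi-allelic evidence is collapsed into one
  non-reference class.
- No base qualities or genotype likelihoods; calling is a pure count
  threshold.
- Sensitivity at chip SNPs inherits the generator's assumption that
  chip SNPs are an unascertained random subset of true SNPs; real chip
  panels are biased toward common, intermediate-frequency variants.
- The exponential-block divergence model is a caricature of linkage
  disequilibrium: it has a single spatial scale and no recombination
  gradient, so per-class differences in the optimal window arise only
  from sampling noise unless block lengths are configured per
  chromosome class.
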