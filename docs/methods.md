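# Methods

## Scope and model

`nicscreen` analyses shallow whole-genome sequencing of embryo liquid
biopsies (spent culture medium, blastocoel fluid) and of cell-based
references (inner cell mass, whole blastocyst) for chromosome copy-number
state. The unit of analysis is the 1 Mb genomic bin; the signal is the
normalized copy ratio r per bin, with the linear dosage model

    E[r] = cn_eff / 2,      cn_eff = 2 + m · (cn − 2)

for an event to copy number `cn` present in a cellular fraction `m`
(m = 1 is a full, non-mosaic aneuploidy). A trisomy therefore sits at
r = 1.5, a monosomy at 0.5, and a 60% mosaic trisomy at 1.3. All
segmentation and calling operate on this linear ratio scale so that the
±50% whole-copy shifts are literal; running CBS on log₂ ratios would be an
equally defensible convention, but the linear scale keeps the mixture
inversion m̂ = 2·|r − 1| exact rather than approximate.

## Synthetic data generator

The generator produces per-bin integer read counts with the features of
WGA'd shallow sequencing that the analysis has to survive. It emulates:

- **Genome**: 24 chromosomes with a built-in human-like length table
  (3,086 Mb total; compiled in, nothing downloaded). A `scale` parameter
  shrinks all chromosomes proportionally for fast tests. GC per bin follows
  a seeded AR(1) field (mean 0.41, stationary SD 0.05, lag-1 correlation
  0.85, clipped to [0.2, 0.8]). The correlation is deliberately short-range:
  if GC were near-constant within a chromosome, GC and chromosome identity
  would be confounded and GC correction could absorb real whole-chromosome
  signal.
- **Dosage**: per-bin effective copy number from the constitutional sex
  (XX/XY) plus events, interpolated by the mosaic fraction; optional
  mixing with a 46,XX contaminant (fraction c of reads), emulating maternal
  cell contamination.
- **Coverage bias**: a multiplicative log-linear GC bias
  exp(s·(gc − 0.41)), strength s per source profile.
- **Counting noise**: negative-binomial counts with var = μ(1 + α·μ);
  α → 0 recovers Poisson. A single overdispersion knob is the simplest model
  that reproduces the qualitative difference between DNA sources; no
  published noise model exists for this assay, so α values are plausible
  settings, not fits.
- **Dropout and technical failure**: a per-bin zeroing probability; a
  sample whose nonzero-bin fraction falls below 0.8 (configurable) is
  flagged "no result", mirroring the technical-success notion of the assay.
- **Read depth**: raw draws are rescaled by largest-remainder rounding so
  each sample's counts sum exactly to the profile's `total_reads`.

Default source profiles (2,000,000 reads unless noted):

| source | reads | dispersion α | GC strength | dropout | rationale |
|--------|-------|--------------|-------------|---------|-----------|
| SCM    | 2e6   | 0.01         | 1.0         | 0       | full yield, WGA overdispersion |
| BF     | 1e6   | 0.05         | 1.0         | 0.10    | ~5-fold lower DNA input: fewer effective reads, noisier, patchier |
| ICM/WB | 2e6   | 0.002        | 0.5         | 0       | cell-based reference, cleaner amplification |

Cohorts default to n = 148 embryos with aneuploidy rate 47/148 (≈31.8%),
matching the validation-cohort composition the fixtures encode; aneuploid
truths carry one random whole-autosome gain or loss, mosaic with
probability 0.2 with m uniform on (0.5, 0.95).

What the generator does **not** emulate: read-level artifacts (mappability,
duplicates), fragment-size structure of cell-free DNA, WGA chemistry
(allele dropout at the locus level), segmental-event size distributions,
and real GC tracks. Passing recovery tests therefore demonstrates that the
analysis correctly inverts the generative model it assumes — not that it
would meet the same accuracy on real amplified cfDNA, whose noise is
heavier-tailed and locus-correlated.

## Normalization

1. **Bin filtering** — bins are masked if flagged unusable, outside the GC
   range [0.2, 0.8], below the panel-median floor (0.1), or zero-count.
   More than 50% of autosomal bins masked ⇒ the sample is "not analyzable"
   (the technical-failure category).
2. **GC correction** — robust lowess (span 0.3, 2 robustness iterations) of
   log₂ depth on GC over valid autosomal bins, evaluated everywhere by
   interpolation; the fitted trend is divided out and the mean autosomal
   depth preserved. For speed the trend is fitted on at most 2,000
   evenly-spaced (in GC order) bins — the trend is 1-dimensional and smooth,
   so this loses nothing measurable.
3. **Reference panel** — each euploid panel sample is scaled to its
   autosomal median; per-bin medians are taken across all samples on
   autosomes and within XX / XY subsets on the sex chromosomes (the Y has no
   baseline in an XX panel, so Y medians come from XY samples only). Bins
   with across-panel CV > 0.3 or non-positive median are masked. Panel
   sexes are inferred from relative Y coverage when not given.
4. **Ratio and anchoring** — sample depth / panel median, then divided by
   the median over valid autosomal bins so the autosomal median is exactly
   1. The median (not the mean) is the anchor because a single aneuploid
   chromosome perturbs the mean but not the median of ~2,900 autosomal bins.

A sample is normalized against both panel branches; the X dosage against
the XX branch (≈1 for XX, ≈0.5 for XY) together with the Y dosage against
the XY branch (≈1 if a Y is present, ≈0 otherwise) selects the sex model,
with windows X∈[0.8, 1.2] vs X∈[0.35, 0.65] and a Y-presence threshold of
0.5; disagreement yields an indeterminate sex.

## Segmentation (CBS)

The change-point statistic is the canonical circular one: for an arc (i, j]
of the chromosome's ratio vector, the pooled two-sample t between the arc
and its complement, maximized over all arcs. Wrapping arcs are not
enumerated separately because a wrapped arc and its complement give the
same |T|; ties between an arc and its complement (or any numerical tie,
within a 1e-12 relative band) resolve to the smallest i, then smallest j.
A perfect two-level split (zero pooled variance, nonzero contrast) scores
T = +∞; a constant vector scores 0.

Significance comes from a within-chromosome permutation test,
p = (1 + #{perm max|T| ≥ T_obs}) / (n_perm + 1), with defaults α = 0.01 and
n_perm = 1000. Permuting within the chromosome preserves its noise scale.
Significant arcs split the vector recursively; no resulting segment may be
shorter than min_width = 3 bins. Adjacent segments whose means differ by
less than 0.1 (ratio units) are merged with bin-weighted means.

Two numerical choices matter for throughput. The permutation loop evaluates
max|T| per permutation via a per-arc-length sweep (for fixed length the
statistic is monotone in the arc sum, so only the extreme windowed sums per
length need scoring), batched 64 permutations at a time. And the loop stops
early as soon as the exceedance count already guarantees p ≥ α — the
accept/reject decision is provably identical to the full run, but a null
chromosome costs a few dozen permutations instead of 1000. Both paths are
cross-checked against an exhaustive O(n²) enumeration in the tests.

## Calling

Per chromosome, the dominant deviating segment (largest |mean − 1|) drives
the call, with m̂ = 2·|mean − 1| clamped to [0, 1]:

- m̂ < 0.5 — euploid (below the mosaicism reporting floor);
- segment spans ≥ 80% of the chromosome's bins and m̂ ≥ 0.8 — full
  gain/loss with integer copy number (karyotype e.g. `47,XY,+21`);
- spans ≥ 80% and 0.5 ≤ m̂ < 0.8 — mosaic gain/loss, reported with the
  fraction (`46,XX,+16[0.6]`);
- a sub-chromosomal segment of ≥ 10 bins with m̂ ≥ 0.5 — segmental event
  (`46,XY,dup(7)[0.8]`).

The 0.5 reporting floor is the assay's stated convention. The 0.8
full-vs-mosaic cutoff exists only because integer copy numbers must be
printed somewhere; it is configurable. The 10-bin (≈10 Mb) minimum for
reporting segmental events reflects the practical resolution of 1 Mb-bin
screening: occasional 3–4-bin noise runs can reach nominal significance in
an overdispersed sample, and a ~10 Mb floor is the standard guard against
them. Any abnormal chromosome classifies the sample as aneuploid/mosaic
(the positive class of every diagnostic metric); technical failures are
"no result" and are excluded from all concordance denominators.

## Diagnostics

Confusion matrices use aneuploid/mosaic as the positive class; metrics are
kept as exact fractions and displayed as half-up-rounded percentages with
one decimal (so 41/80 prints as 51.3%). Metrics with zero denominators are
undefined (None), never zero. Subgroup matrices pool cellwise. The 2×2 χ²
test (scipy, 1 df) is exposed both with and without Yates continuity
correction — published tables of this kind rarely state which convention
produced each P value, and the two differ materially in small cells — with
the correction on by default.

The packaged fixture sheets are synthetic row-level reconstructions of a
published validation cohort's printed summary counts (148 triads scored
against ICM/WB references; 212 embryos with per-insemination sex and ploidy
concordance; 64 WB–SCM pairs). Which individual rows are discordant is
arbitrary — only the marginals are data — and the raw study data is
access-restricted, so these sheets exercise the diagnostics stage end to
end without any download.

## Problem sizes and determinism

Tests and the acceptance script run the full 3,086-bin genome at 2×10⁶
reads for linearity and cohort-recovery checks (a 20-sample panel, a
148-embryo cohort), and proportionally scaled genomes (`scale` = 0.05–0.2)
for unit tests. Every stochastic component takes an explicit seed —
generator, permutation tests, per-chromosome and per-sample child seeds are
derived deterministically — so (config, seed) fixes every downstream
number.

## Known limitations

- Uniform ploidy changes (triploidy, haploidy) scale all bins equally and
  are invisible to ratio-based methods; they are out of scope.
- Mosaic fractions just above the 0.5 floor are intrinsically borderline:
  with chromosome-mean noise of ~1–3%, events at m ≈ 0.50–0.55 fall below
  the floor in a material fraction of runs. This is a property of the
  assay's reporting rule, not of the implementation.
- Sub-chromosomal events smaller than ~10 Mb are deliberately not reported.
- The normalization matches the stated contract of proprietary clinical
  pipelines (GC + reference-panel normalization) at the level of behavior,
  not bit-for-bit internals.
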