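# nicscreen

Non-invasive chromosome screening (NICS) of embryo liquid biopsies from
shallow whole-genome sequencing read counts.

In IVF, pre-implantation genetic testing for aneuploidies (PGT-A) normally
requires an embryo biopsy. Non-invasive alternatives sequence the cell-free
DNA an embryo sheds into its spent culture medium (SCM) or blastocoel fluid
(BF) and ask whether each chromosome is present in the normal two copies.
`nicscreen` implements that analysis as a tested, reproducible pipeline —
and, because the raw clinical data behind such studies is access-restricted,
it ships a read-count simulator that generates cohorts with the same
statistical structure, so every stage can be validated against known ground
truth.

## What it computes

Reads are counted in 1 Mb bins (~3,100 bins genome-wide, ~2×10⁶ reads per
sample). Per-bin counts are GC-corrected (robust lowess of log₂ depth on GC),
divided by the per-bin medians of a euploid reference panel, and anchored so
the median autosomal copy ratio r = 1. On this scale copy number is linear:

- a chromosome at three copies shifts its mean ratio to r = 1.5 (+50%),
- one copy shifts it to r = 0.5 (−50%),
- a mosaic abnormality in a fraction *m* of cells sits at r = 1 ± m/2.

Circular binary segmentation (CBS) — the maximal arc t statistic with
within-chromosome permutation p-values, implemented from scratch — partitions
each chromosome into constant-mean segments. Segments are converted to
per-chromosome calls by inverting the mixture, m̂ = 2·|r − 1|; mosaicism is
reported only at m ≥ 0.5, and any abnormal chromosome makes the sample
**aneuploid/mosaic**. Sex is called from X/Y dosage. Calls are scored against
a gold-standard reference (inner cell mass or whole blastocyst) with the
standard screening metrics — sensitivity TP/(TP+FN), specificity TN/(TN+FP),
NPV TN/(TN+FN), PPV TP/(TP+FP), two-category concordance (TP+TN)/n — plus
χ² comparisons between assays.

## Worked example

```python
import nicscreen as ns

genome = ns.build_genome(seed=1)                       # 3,086 one-Mb bins
profile = ns.DEFAULT_PROFILES["SCM"]                   # 2e6 reads, WGA noise

# euploid reference panel -> fitted normalizer
panel, _ = ns.simulate_reference_panel(20, profile, genome, seed=5)
screen = ns.AneuploidyScreen(genome=genome, random_state=7).fit(panel)

# an embryo with trisomy 21 in 60% of cells
sl = genome.chrom_slice("21")
truth = ns.SampleKaryotype("XY", (ns.CnvEvent("21", 0, sl.stop - sl.start, 3, 0.6),))
sample = ns.simulate_sample(truth, profile, genome, seed=11)

call = screen.screen_one(sample)
print(call.classification)   # aneuploid/mosaic
print(call.karyotype)        # 46,XY,+21[0.55]
print(call.sex)              # XY
```

The mosaic fraction printed in brackets (0.55 here) is the estimate
m̂ = 2·|r − 1| recovered from the chromosome's segment mean — within noise of
the simulated 0.6. `AneuploidyScreen` follows scikit-learn conventions
(`fit` on a panel count matrix, `predict` returning labels), so it composes
with sklearn tooling; `CopyRatioNormalizer` is the corresponding transformer.

A command line covers the same pipeline over files:

```bash
nicscreen simulate --config config.yaml --out cohort/
nicscreen normalize --genome cohort/genome.tsv --panel-dir cohort/panel \
    --out-dir ratios/ cohort/SCM/*.tsv
nicscreen segment --genome cohort/genome.tsv --out-dir segs/ ratios/*.tsv
nicscreen call --genome cohort/genome.tsv --seg-dir segs/ --out calls.csv ratios/*.tsv
nicscreen evaluate --calls calls.csv --truth cohort/truth.csv --out report.json
```

`nicscreen evaluate` on the packaged validation-cohort fixture sheets
(`nicscreen.load_fixture("cohort148_truth")`, ...) reproduces a published
148-embryo SCM/BF concordance table without any simulation.

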