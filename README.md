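# mitoribo

A ribosome-profiling analysis pipeline for cell-cycle comparisons of mRNA
translation, built for the G2 → M → G1 window where translation, not
transcription, dominates gene regulation.

During mitosis, bulk translation drops by a modest global factor (~35%),
while a small set of specific mRNAs is much more strongly (>3-fold)
translationally repressed and re-activated at mitotic exit.  Distinguishing
those two programs from sequencing data requires careful normalisation:
profiling only reports *relative* densities, so the global scalar cancels
and only gene-specific changes are detectable.  `mitoribo` implements that
analysis as a reusable, tested library plus CLI, and ships a planted-truth
simulator so every stage can be validated against known answers.

## What it computes

For footprint (FP) and mRNA libraries across G2, M and G1 (two biological
replicates each):

* **P-site densities** — per-read-length offsets calibrated from the
  start-codon metagene pile-up (mode of `cds_start − 5′ end`; ties to the
  smallest offset; stop-codon cross-check), then CDS-restricted per-gene
  counts.
* **RPKM** — `reads / (kb of feature) / (millions of mapped reads)`, with
  the CDS as feature for FP and the transcript for mRNA.
* **Translation efficiency** — `TE = RPKM_FP / RPKM_mRNA` after replicate
  merging and the depth/concordance filters: >200 summed reads per library,
  replicate RPKM ratio ≤ 3, ≥200 mRNA reads for TE.
* **Regulation calls** — between an ordered phase pair (A, B), `mRNA
  up/down` at a strict >3-fold RPKM ratio; `TE repressed/activated` at the
  dual threshold >3-fold TE **and** >2-fold FP RPKM in the same direction.
* **Summaries** — per-comparison call histograms, overlap fractions between
  comparisons, per-phase gene-set medians, log2 fold–fold correlations,
  FP-only fold tables for poly(A)-minus genes (histones), and replicate QC
  (R², SD of log2 replicate ratios, the fold at 6 SD).
* **Live-cell reporter rates** — from dual-colour degron-reporter traces:
  flat-field, bleach and background corrections, then the per-cell
  normalised rate `Δ(GFP/mCherry)/Δt` (h⁻¹) and mitosis/interphase ratios
  of group means with cross-experiment SEM.

The simulator (`mitoribo.simulate`) generates transcript annotations,
negative-binomial FP/mRNA counts with planted global and gene-specific
regulation, footprint positions with planted P-site offsets, and reporter
traces — all with recorded ground truth and bit-reproducible seeding.

## Worked example

```python
import mitoribo as mr

cfg = mr.SimulationConfig(n_genes=2000, seed=1)   # study-scale defaults
tx = mr.generate_transcriptome(cfg)
truth = mr.simulate_expression(cfg, tx)
expr = mr.add_rpkm(mr.simulate_counts(truth, tx, cfg), tx)
meas = mr.compute_te(mr.merge_and_filter(expr))

calls = mr.call_te_regulation(meas, "G2", "M")
print(calls["te_class"].value_counts().to_string())

rep = calls.index[calls["te_class"] == "repressed"]
print(mr.gene_set_medians(meas, rep, "te").round(3).to_string())

calls_g1 = mr.call_te_regulation(meas, "G1", "M")
ov = mr.overlap_fraction(calls, calls_g1, "repressed", "te", 2.0)
print(f"{100*ov:.1f}%")
```

prints

```
te_class
unchanged    1484
filtered      390
repressed     107
activated      19
phase
G2    1.142
M     0.289
G1    1.166
100.0%
```

Reading this: of 2000 simulated genes, 390 fail the read-depth or
replicate-concordance filters; 107 are called translationally repressed in
M versus G2 and 19 activated (the planted majority-repression asymmetry).
The repressed set's median TE drops ~4-fold in M and recovers in G1 —
repression at mitotic entry, re-activation at exit — and every one of those
genes is also >2-fold repressed in M relative to G1.

The same analysis is available from the shell:

```sh
mitoribo --seed 1 run --outdir run1          # full synthetic pipeline
mitoribo --seed 1 simulate --outdir sim      # just the synthetic dataset
mitoribo calibrate sim/footprints.bed sim/annotation.tsv --out offsets.json
mitoribo quantify sim/footprints.bed sim/annotation.tsv --offset-table offsets.json
mitoribo te run1/expression.tsv
mitoribo call gene_measurements.tsv --phase-a G2 --phase-b M
mitoribo reporter traces.csv
```

`run` writes every intermediate table (annotation, ground truth,
calibration footprints, expression, measurements, calls, QC) plus a
`manifest.json` recording versions, seed, thresholds and per-stage counts;
reruns with the same configuration are byte-identical.

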