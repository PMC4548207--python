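# Methods

## The measurement model

Ribosome profiling counts ~30 nt ribosome-protected mRNA fragments
(footprints, FP); in parallel, RNA-seq counts fragments of total poly(A)
mRNA.  For a gene *g* in sample *s*, densities are expressed as RPKM,

    RPKM_gs = reads_gs / (L_g / 10^3) / (N_s / 10^6),

with `L_g` the CDS length for footprint libraries and the full transcript
length for mRNA libraries, and `N_s` the sample's total uniquely mapped
reads.  Translation efficiency is the density ratio

    TE_g = RPKM^FP_g / RPKM^mRNA_g,

the average ribosome load per unit mRNA.  Because each sample is normalised
to its own sequencing depth, RPKM and TE are *relative* measures: a scalar
repression acting uniformly on all mRNAs (such as the ~35% global
translational repression of mitosis) cancels exactly and is invisible to
within-sample comparisons.  Only gene-specific deviations from the sample
average are detectable, which is the quantity of interest here.

## P-site assignment

The distance from a footprint's 5′ end to the ribosomal P-site depends on
read length.  `calibrate_psite_offsets` estimates one offset per read
length as the mode of `cds_start − five_prime_pos` over reads whose 5′ end
falls within one read length upstream of annotated start codons; the
initiation-site pile-up makes the true offset modal.  Ties break to the
smallest offset (deterministic).  The same statistic at the last CDS codon
serves as a cross-check and disagreements are logged; the start-codon
estimate is authoritative.  Lengths with fewer than `min_reads_per_length`
(default 100) reads in the window are omitted.  `assign_psites` then counts
a read for its gene iff `five_prime_pos + offset` lies inside
`[cds_start, cds_end)`; reads of uncalibrated length or with extra-CDS
P-sites are dropped and logged.  All coordinates are 0-based, half-open.

## Filtering and calls

Per phase and library type, reads are summed over the two biological
replicates; genes are kept only when (a) the sum strictly exceeds
`min_reads` = 200 and (b) the replicate RPKM ratio (max/min, direction-free)
does not exceed `max_replicate_fold` = 3.  One zero-RPKM replicate counts
as discordant; two zeros fall to the read floor.  Surviving RPKMs are
arithmetically averaged.  TE additionally requires *at least* 200 mRNA
reads (≥, versus the strictly-greater general floor; the two rules differ
only at exactly 200 reads, where the general floor already excludes the
gene).  Both thresholds are configurable.

Between an ordered phase pair (A, B), with folds computed A/B on
replicate-averaged linear-scale values:

* mRNA-level change: `down` in B iff fold > 3, `up` iff inverse fold > 3;
  boundary equality is `unchanged`.  All thresholds are strict.
* TE-level change (dual threshold): `repressed` in B iff the TE fold > 3
  **and** the FP-RPKM fold > 2, both in the same direction; symmetric for
  `activated`.  The FP condition makes a TE change meaningful only when the
  absolute amount of synthesis on the mRNA changes too.

No shrinkage, p-values or multiple-testing correction are applied — calls
are pure fold cutoffs, justified by `replicate_qc`, which reports per-sample
replicate R² on log2 RPKM, the SD of log2(rep1/rep2), and the fold
corresponding to 6 SD; a 3-fold cutoff should sit well above that yardstick.
Overlap fractions between comparisons (e.g. repressed at mitotic entry vs
repressed relative to G1) are computed over genes with a defined fold in the
secondary comparison, and fold–fold agreement is summarised by the Pearson
correlation of log2 folds.

## The synthetic experiment

`simulate.py` generates the full study design with recorded ground truth.

* **Transcripts** — CDS lengths uniform over whole codons in 300–6000 nt,
  UTR margins uniform in 30–300 nt per side.  These spans cover typical
  human mRNAs without modelling isoforms.
* **Abundance and TE** — per-gene relative mRNA abundance is lognormal with
  σ(ln) = 1.0 (expression spanning roughly two orders of magnitude, as in
  bulk data); gene-specific TE is lognormal with σ(ln) = 0.5.
* **Planted regulation** — defaults emulate the targeted regime: 10% of
  genes TE-repressed 4-fold in M and 1% TE-activated 4-fold (a 10:1
  asymmetry); 5% of genes with 4-fold mRNA-level changes between G1 and
  G2/M (split evenly up/down, G2 = M by construction); plus a 35% global
  scalar on all M footprint means.  Planted TE folds are exact in the truth
  record; the global scalar is a library property, applied at the count
  stage and *removed again* by library-size renormalisation — so it is only
  observable through the pre-normalisation footprint mass (what an external
  calibration such as metabolic labelling measures), not through RPKM.
* **Counts** — negative binomial with variance μ + μ²·d.  The dispersion
  default d = 0.01 (10% extra-Poisson CV) represents tight biological
  replicates; no published value was available for the replicate series
  being emulated, so the choice is the package's own and is exercised
  directly by the moment tests.  d = 0 falls back to Poisson.
* **Footprint positions** — P-sites uniform over CDS codons with a 5×
  spike at the first and last codon; 5′ ends at P-site − offset(length);
  optional ±1 nt jitter on a configurable fraction of reads.  Used to test
  calibration, not to generate the count tables (counts are drawn directly,
  which is faster and statistically equivalent for downstream stages).
* **Reporter traces** — per-cell GFP follows dG/dt = c·s − k·G with copy
  number c (lognormal, σ configurable), synthesis rate s per hour and decay
  k per hour; mCherry is c × constant.  A constant acquisition background is
  added and recorded; optional multiplicative Gaussian noise.  With GFP(0)=0
  the endpoint-ratio estimator recovers rate *ratios* exactly (the decay
  factor cancels between groups sharing k and window length).

Randomness: one master seed; each stage draws from a child generator seeded
by (master, stage-index), so outputs are bit-reproducible and adding a stage
never perturbs another.

What the generator does **not** emulate: sequence content (no FASTQ, no
aligner), isoforms and overlapping genes, positional biases beyond the
start/stop spikes, batch effects, partial rRNA contamination, or
phase-impurity of the sorted populations.  Passing recovery tests therefore
demonstrates correctness of the quantification and classification logic
under the stated noise model, not robustness to every artefact of real
libraries.

## Reporter quantification

Processing order: flat-field division (gain map normalised to mean 1),
optional photobleach correction (single-exponential decay fitted to a
stable control signal; a non-monotone fit skips the correction with a
warning), per-frame background subtraction, then

    rate = [G/M(t_end) − G/M(t_start)] / (t_end − t_start)   [h⁻¹],

with endpoint ratios averaged over the first/last 2 frames by default
(single-frame endpoints available; the mode is recorded in the output).
Scaling a cell's two channels by any constant leaves its rate unchanged
(copy-number invariance).  Group ratios are ratios of group means; when
experiment labels are present the SEM across per-experiment ratios is
reported.  Under complete shutdown the rate is slightly negative, since the
existing GFP pool decays while mCherry persists.

## Scoring recovery against planted truth

Sensitivity is reported over *analyzable* planted genes — those passing the
read-depth and concordance filters in both compared phases — and precision
over all called genes; the unconditional recall is reported alongside.
This conditioning is deliberate: a 4-fold repressed gene loses 4-fold of
its M footprint reads, so at study-scale depth (~2×10⁶ reads over 2000
genes) a sizeable fraction of planted repressed genes falls below the
200-read floor and is unmeasurable *by construction*, exactly as such genes
would be absent from a real study's gene lists.  The same censoring is why
the called repressed:activated ratio (~5–6:1 at these settings) undershoots
the planted 10:1 asymmetry — repressed genes are preferentially censored,
activated genes almost never — so the asymmetry check compares the called
repressed fraction with the planted fraction among analyzable genes, within
binomial error.

## Numerical and degenerate-input choices

* Fold thresholds are strict (>); equality is `unchanged`.
* Offset-mode ties take the smallest offset.
* TE is NaN (a value, not an error) when blocked; classes become
  `filtered` whenever any contributing quantity is undefined.
* Zero totals, non-positive gains, non-positive reference means, and empty
  gene sets raise immediately with specific messages.
* RPKM conservation, Σ RPKM·(L/10³) = 10⁶·(counted/total), holds to float
  round-off and is asserted in the tests.

## Problem sizes

The shipped study configuration uses 2000 genes, 2 replicates, 2×10⁶ reads
per library, 1.5×10⁵ calibration footprints, and 10–200 reporter cells;
the whole test suite and the acceptance script each complete in well under
a minute.  All sizes are configuration fields and scale linearly.
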