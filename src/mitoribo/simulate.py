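"""Synthetic ribosome-profiling data with planted ground truth.

This module emulates the statistical structure of a cell-cycle ribosome
profiling experiment: a few thousand transcripts measured in G2, mitosis (M)
and G1 with two biological replicates each of a footprint (FP) and an mRNA
library.  Three layers of regulation are planted and recorded:

* a *global* scalar repression of all footprint densities in M (default 35%),
  which — because sequencing depth is arbitrary and samples are renormalised
  to a configured library size — is invisible to within-sample relative
  measures, exactly as in real profiling data;
* *gene-specific* translation-efficiency (TE) changes in M: a majority of
  planted genes repressed and a small minority activated, by a configurable
  fold (> 3 by default);
* mRNA-level changes between G1 and G2/M for a distinct planted subset.

Counts are drawn from a negative binomial with variance ``mu + mu**2 * disp``,
the standard overdispersed replicate model for sequencing counts.  Footprint
read *positions* (for P-site offset calibration) and dual-colour reporter
fluorescence traces (for the live-cell rate estimator) are simulated by
separate generators.  All randomness derives from a single master seed via
fixed per-stage child seeds, so identical configurations give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PHASES: tuple[str, str, str] = ("G2", "M", "G1")
LIBRARIES: tuple[str, str] = ("FP", "mRNA")

#: class labels recorded in the ground truth
TE_REPRESSED = "te_repressed_M"
TE_ACTIVATED = "te_activated_M"
MRNA_REGULATED = "mrna_regulated_G1"
BACKGROUND = "background"

# fixed per-stage seed offsets (master seed + stage key -> child generator)
_STAGES = {
    "transcriptome": 1,
    "expression": 2,
    "counts": 3,
    "positions": 4,
    "reporter": 5,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the study regime the pipeline targets: ~2000 genes,
    two replicates, ~2 million reads per library, a 35% global repression of
    translation in mitosis, ~10% of genes translationally repressed four-fold
    in M against ~1% activated (a ~10:1 asymmetry), and a distinct subset
    with four-fold mRNA-level differences between G1 and G2/M.
    """

    n_genes: int = 2000
    n_replicates: int = 2
    library_size_fp: int = 2_000_000
    library_size_mrna: int = 2_000_000
    global_m_repression: float = 0.35
    frac_te_repressed: float = 0.10
    frac_te_activated: float = 0.01
    te_fold: float = 4.0
    frac_mrna_regulated_g1: float = 0.05
    mrna_fold: float = 4.0
    dispersion: float = 0.01
    psite_offsets: Mapping[int, int] = field(
        default_factory=lambda: {28: 12, 29: 12, 30: 13}
    )
    seed: int = 0
    # transcript geometry: CDS length uniform over whole codons in
    # [cds_nt_range], UTR margins uniform in [utr_nt_range] on each side
    cds_nt_range: tuple[int, int] = (300, 6000)
    utr_nt_range: tuple[int, int] = (30, 300)
    # metagene spike at the first and last CDS codon, relative to the
    # uniform per-codon density; used only to exercise offset calibration
    start_stop_enrichment: float = 5.0
    # lognormal spread (sigma of ln) of per-gene mRNA abundance and TE
    abundance_sigma: float = 1.0
    te_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.library_size_fp <= 0 or self.library_size_mrna <= 0:
            raise ConfigurationError("library sizes must be > 0")
        if not 0.0 <= self.global_m_repression < 1.0:
            raise ConfigurationError("global_m_repression must be in [0, 1)")
        fracs = (
            self.frac_te_repressed,
            self.frac_te_activated,
            self.frac_mrna_regulated_g1,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError("planted fractions must be in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ConfigurationError("planted fractions must sum to <= 1")
        if self.te_fold <= 1.0 or self.mrna_fold <= 1.0:
            raise ConfigurationError("planted folds must be > 1")
        if self.dispersion < 0.0:
            raise ConfigurationError("dispersion must be >= 0")
        for length, off in self.psite_offsets.items():
            if not 0 <= off < length:
                raise ConfigurationError(
                    f"P-site offset {off} invalid for read length {length}"
                )
        lo, hi = self.cds_nt_range
        if lo < 3 or hi < lo:
            raise ConfigurationError("cds_nt_range invalid")
        if self.utr_nt_range[0] < 0 or self.utr_nt_range[1] < self.utr_nt_range[0]:
            raise ConfigurationError("utr_nt_range invalid")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage child generator from the master seed."""
        return np.random.default_rng([int(self.seed), _STAGES[stage]])

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def generate_transcriptome(config: SimulationConfig) -> pd.DataFrame:
    """Draw a synthetic transcript annotation.

    Returns a frame indexed by ``transcript_id`` with columns ``length``,
    ``cds_start``, ``cds_end`` (0-based, half-open; CDS length a whole number
    of codons; UTR margins of at least the configured minimum on both sides).
    """
    rng = config.rng("transcriptome")
    n = config.n_genes
    lo_codons = -(-config.cds_nt_range[0] // 3)  # ceil to whole codons
    hi_codons = config.cds_nt_range[1] // 3
    cds_len = 3 * rng.integers(lo_codons, hi_codons + 1, size=n)
    utr5 = rng.integers(config.utr_nt_range[0], config.utr_nt_range[1] + 1, size=n)
    utr3 = rng.integers(config.utr_nt_range[0], config.utr_nt_range[1] + 1, size=n)
    ids = [f"g{i:05d}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "length": utr5 + cds_len + utr3,
            "cds_start": utr5,
            "cds_end": utr5 + cds_len,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    return frame


def simulate_expression(
    config: SimulationConfig, transcriptome: pd.DataFrame
) -> pd.DataFrame:
    """Plant per-gene true abundances, TEs and regulation classes.

    Returns the ground-truth frame indexed by gene with columns ``label``,
    ``mrna_<phase>`` (relative mRNA abundance) and ``te_<phase>``
    (gene-specific TE).  The global mitotic repression scalar is *not*
    folded into ``te_M``: it is a property of the M footprint libraries,
    applied in :func:`simulate_counts`, and background genes therefore carry
    identical true TE across phases up to that scalar.
    """
    if len(transcriptome) != config.n_genes:
        raise ConfigurationError("transcriptome size does not match config")
    rng = config.rng("expression")
    n = config.n_genes

    n_rep = round(config.frac_te_repressed * n)
    n_act = round(config.frac_te_activated * n)
    n_mrna = round(config.frac_mrna_regulated_g1 * n)
    order = rng.permutation(n)
    labels = np.array([BACKGROUND] * n, dtype=object)
    labels[order[:n_rep]] = TE_REPRESSED
    labels[order[n_rep : n_rep + n_act]] = TE_ACTIVATED
    labels[order[n_rep + n_act : n_rep + n_act + n_mrna]] = MRNA_REGULATED

    base_mrna = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    base_te = rng.lognormal(mean=0.0, sigma=config.te_sigma, size=n)
    up_in_g1 = rng.random(n) < 0.5  # direction of planted mRNA changes

    mrna = {p: base_mrna.copy() for p in PHASES}
    te = {p: base_te.copy() for p in PHASES}

    is_rep = labels == TE_REPRESSED
    is_act = labels == TE_ACTIVATED
    te["M"][is_rep] = base_te[is_rep] / config.te_fold
    te["M"][is_act] = base_te[is_act] * config.te_fold

    is_m = labels == MRNA_REGULATED
    up = is_m & up_in_g1
    down = is_m & ~up_in_g1
    mrna["G1"][up] = base_mrna[up] * config.mrna_fold
    mrna["G1"][down] = base_mrna[down] / config.mrna_fold

    truth = pd.DataFrame({"label": labels}, index=transcriptome.index.rename("gene"))
    for p in PHASES:
        truth[f"mrna_{p}"] = mrna[p]
    for p in PHASES:
        truth[f"te_{p}"] = te[p]
    return truth


def footprint_mean_weights(
    truth: pd.DataFrame, transcriptome: pd.DataFrame, config: SimulationConfig, phase: str
) -> pd.Series:
    """Un-normalised expected footprint read mass per gene for one phase.

    Proportional to mRNA abundance x gene-specific TE x CDS length, and in M
    additionally scaled by ``1 - global_m_repression``.  Sums across genes
    therefore expose the global repression *before* library-size
    renormalisation (the quantity an external calibration such as metabolic
    labelling would see), while the renormalised counts do not.
    """
    w = (
        truth[f"mrna_{phase}"]
        * truth[f"te_{phase}"]
        * (transcriptome["cds_end"] - transcriptome["cds_start"])
    )
    if phase == "M":
        w = w * (1.0 - config.global_m_repression)
    return w


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + mu^2*dispersion (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    truth: pd.DataFrame, transcriptome: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Draw the full count table: gene x phase x replicate x library.

    Expected counts are proportional to true abundance x feature length
    (CDS for FP after TE and global-repression scaling, full transcript for
    mRNA), renormalised per sample to the configured library size, then drawn
    from the negative binomial.  Returns a tidy frame with columns
    ``gene, phase, replicate, library, reads``.
    """
    if config.dispersion <= 0.0 and config.dispersion != 0.0:
        raise ConfigurationError("dispersion must be >= 0")
    rng = config.rng("counts")
    tlen = transcriptome["length"]
    rows = []
    for phase in PHASES:
        fp_w = footprint_mean_weights(truth, transcriptome, config, phase)
        mrna_w = truth[f"mrna_{phase}"] * tlen
        means = {
            "FP": fp_w / fp_w.sum() * config.library_size_fp,
            "mRNA": mrna_w / mrna_w.sum() * config.library_size_mrna,
        }
        for library in LIBRARIES:
            mu = means[library].to_numpy()
            for rep in range(1, config.n_replicates + 1):
                reads = _nb_draw(rng, mu, config.dispersion)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene": truth.index,
                            "phase": phase,
                            "replicate": rep,
                            "library": library,
                            "reads": reads,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def simulate_footprint_positions(
    truth: pd.DataFrame,
    transcriptome: pd.DataFrame,
    config: SimulationConfig,
    n_reads: int = 200_000,
    phase: str = "G2",
    shift_noise_frac: float = 0.0,
) -> pd.DataFrame:
    """Simulate individual footprint alignments in transcript coordinates.

    P-sites are uniform over CDS codons with a ``start_stop_enrichment``-fold
    spike at the first and last codon; read lengths are drawn uniformly from
    the configured offset table and each 5' end is placed at
    ``P-site - offset[length]``.  ``shift_noise_frac`` of reads are shifted
    by +/-1 nt to emulate imprecise nuclease trimming.  Reads that would
    extend beyond the transcript are dropped.  Genes whose transcript cannot
    hold any configured read length are skipped.

    Returns a frame with columns ``transcript_id, five_prime_pos,
    read_length``.
    """
    rng = config.rng("positions")
    lengths = np.array(sorted(config.psite_offsets), dtype=int)
    offsets = np.array([config.psite_offsets[l] for l in lengths], dtype=int)

    ok = transcriptome["length"] >= lengths.max()
    if not ok.all():
        import warnings

        warnings.warn(
            f"{(~ok).sum()} transcripts shorter than the longest read were skipped"
        )
    tx = transcriptome.loc[ok]
    w = footprint_mean_weights(truth.loc[ok.index[ok]], tx, config, phase)
    gene_idx = rng.choice(len(tx), size=n_reads, p=(w / w.sum()).to_numpy())

    cds_start = tx["cds_start"].to_numpy()[gene_idx]
    cds_end = tx["cds_end"].to_numpy()[gene_idx]
    tlen = tx["length"].to_numpy()[gene_idx]
    n_codons = (cds_end - cds_start) // 3

    # codon sampling with weight E at first and last codon, 1 elsewhere
    enrich = config.start_stop_enrichment
    total_w = (n_codons - 2) + 2 * enrich
    r = rng.random(n_reads) * total_w
    codon = np.where(
        r < enrich,
        0,
        np.where(r < 2 * enrich, n_codons - 1, np.minimum((r - 2 * enrich).astype(int) + 1, n_codons - 2)),
    )
    psite = cds_start + 3 * codon

    li = rng.integers(0, len(lengths), size=n_reads)
    read_length = lengths[li]
    five_prime = psite - offsets[li]

    if shift_noise_frac > 0.0:
        noisy = rng.random(n_reads) < shift_noise_frac
        shift = rng.choice([-1, 1], size=n_reads)
        five_prime = np.where(noisy, five_prime + shift, five_prime)

    keep = (five_prime >= 0) & (five_prime + read_length <= tlen)
    return pd.DataFrame(
        {
            "transcript_id": tx.index.to_numpy()[gene_idx[keep]],
            "five_prime_pos": five_prime[keep],
            "read_length": read_length[keep],
        }
    )


def simulate_reporter_traces(
    n_cells: int,
    rate_interphase: float,
    rate_mitosis: float,
    copy_number_spread: float = 0.5,
    decay_rate: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_min: float = 180.0,
    interval_min: float = 10.0,
    gfp0_per_copy: float = 0.0,
    mcherry_per_copy: float = 100.0,
    background: float = 10.0,
    n_experiments: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate dual-colour translation-reporter time series.

    Each cell carries a lognormally distributed reporter copy number ``c``.
    GFP follows synthesis-minus-first-order-decay dynamics
    ``dG/dt = c*s - k*G`` (``s`` the per-copy synthesis rate in units/h,
    ``k = decay_rate`` per hour), starting from ``c * gfp0_per_copy``;
    mCherry is ``c * mcherry_per_copy``, constant in time.  A constant
    acquisition background is added to both channels and recorded in the
    ``bg_*`` columns, and multiplicative Gaussian noise of relative standard
    deviation ``noise_sd`` perturbs the signals.  Half the cells are labelled
    interphase, half mitosis.

    Returns ``(traces, truth)``: a tidy per-timepoint frame with columns
    ``cell_id, experiment, phase, time_min, gfp, mcherry, bg_gfp,
    bg_mcherry`` and a per-cell truth frame with the planted rate and copy
    number.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if rate_interphase < 0 or rate_mitosis < 0 or decay_rate < 0:
        raise ConfigurationError("rates must be >= 0")
    rng = np.random.default_rng([int(seed), _STAGES["reporter"]])

    t = np.arange(0.0, duration_min + 1e-9, interval_min)
    th = t / 60.0
    phases = np.array(
        ["interphase" if i < (n_cells + 1) // 2 else "mitosis" for i in range(n_cells)]
    )
    rates = np.where(phases == "interphase", rate_interphase, rate_mitosis)
    copies = rng.lognormal(mean=0.0, sigma=copy_number_spread, size=n_cells)
    experiments = np.arange(n_cells) % n_experiments + 1

    rows, truth_rows = [], []
    for i in range(n_cells):
        c, s, k = copies[i], rates[i], decay_rate
        if k > 0:
            gfp = c * (s / k) * (1.0 - np.exp(-k * th)) + c * gfp0_per_copy * np.exp(
                -k * th
            )
        else:
            gfp = c * s * th + c * gfp0_per_copy
        mch = np.full_like(th, c * mcherry_per_copy)
        if noise_sd > 0:
            gfp = gfp * (1.0 + noise_sd * rng.standard_normal(len(th)))
            mch = mch * (1.0 + noise_sd * rng.standard_normal(len(th)))
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": f"cell{i:04d}",
                    "experiment": experiments[i],
                    "phase": phases[i],
                    "time_min": t,
                    "gfp": gfp + background,
                    "mcherry": mch + background,
                    "bg_gfp": background,
                    "bg_mcherry": background,
                }
            )
        )
        truth_rows.append(
            {
                "cell_id": f"cell{i:04d}",
                "experiment": experiments[i],
                "phase": phases[i],
                "true_rate": s,
                "copy_number": c,
            }
        )
    traces = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return traces, truth
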