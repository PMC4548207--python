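"""Replicate merging, read-depth/concordance filters, and translation efficiency.

The filtering scheme follows the profiling convention of summing reads over
the two biological replicates and keeping a gene only when (a) the summed
reads exceed a floor (default 200, strictly greater-than) in the library
being considered and (b) the replicate RPKMs agree within a fold window
(default 3x, direction-free).  Surviving RPKMs are the arithmetic mean of
the replicates, and translation efficiency is the ratio of footprint to
mRNA density, additionally requiring at least 200 mRNA reads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FLAG_LOW_FP = "low_reads_fp"
FLAG_LOW_MRNA = "low_reads_mrna"
FLAG_DISC_FP = "replicate_discordant_fp"
FLAG_DISC_MRNA = "replicate_discordant_mrna"


def _replicate_stats(
    sample: pd.DataFrame, n_replicates: int, min_reads: int, max_replicate_fold: float
) -> pd.DataFrame:
    """Per-gene summed reads, mean RPKM and filter flags for one library."""
    reps = sample.pivot_table(
        index="gene", columns="replicate", values="rpkm", aggfunc="first"
    )
    if reps.shape[1] != n_replicates or reps.isna().any().any():
        raise ValueError(
            f"expected {n_replicates} replicates for every gene, "
            f"found columns {list(reps.columns)}"
        )
    total = sample.groupby("gene")["reads"].sum()
    low = total <= min_reads  # strictly "more than min_reads" retained

    rmax = reps.max(axis=1)
    rmin = reps.min(axis=1)
    both_zero = rmax == 0
    any_zero = (rmin == 0) & ~both_zero
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rmax / rmin
    # one zero replicate -> discordant by convention; both zero -> caught by
    # the read floor instead
    discordant = any_zero | (~both_zero & ~any_zero & (ratio > max_replicate_fold))

    return pd.DataFrame(
        {
            "reads_total": total,
            "rpkm_mean": reps.mean(axis=1),
            "low_reads": low,
            "discordant": discordant,
        }
    )


def merge_and_filter(
    expression: pd.DataFrame,
    min_reads: int = 200,
    max_replicate_fold: float = 3.0,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Merge replicates and apply depth and concordance filters.

    ``expression`` is the tidy per-sample table (``gene, phase, replicate,
    library, reads, rpkm``).  Returns one row per gene x phase with columns
    ``fp_reads_total, mrna_reads_total, fp_rpkm_mean, mrna_rpkm_mean, flags``
    where ``flags`` is a semicolon-joined string drawn from
    ``{low_reads_fp, low_reads_mrna, replicate_discordant_fp,
    replicate_discordant_mrna}`` (empty when the gene passes everything).
    """
    out = []
    for phase, by_phase in expression.groupby("phase", sort=False):
        parts = {}
        for library, sample in by_phase.groupby("library", sort=False):
            parts[library] = _replicate_stats(
                sample, n_replicates, min_reads, max_replicate_fold
            )
        fp, mrna = parts["FP"], parts["mRNA"]
        fp, mrna = fp.align(mrna, join="outer", axis=0)
        flags = pd.concat(
            [
                fp["low_reads"].rename(FLAG_LOW_FP),
                mrna["low_reads"].rename(FLAG_LOW_MRNA),
                fp["discordant"].rename(FLAG_DISC_FP),
                mrna["discordant"].rename(FLAG_DISC_MRNA),
            ],
            axis=1,
        ).fillna(True)
        flag_str = flags.apply(lambda r: ";".join(c for c in flags.columns if r[c]), axis=1)
        out.append(
            pd.DataFrame(
                {
                    "gene": fp.index,
                    "phase": phase,
                    "fp_reads_total": fp["reads_total"].to_numpy(),
                    "mrna_reads_total": mrna["reads_total"].to_numpy(),
                    "fp_rpkm_mean": fp["rpkm_mean"].to_numpy(),
                    "mrna_rpkm_mean": mrna["rpkm_mean"].to_numpy(),
                    "flags": flag_str.to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def compute_te(
    measurements: pd.DataFrame, min_mrna_reads_te: int = 200
) -> pd.DataFrame:
    """Attach translation efficiency to a merged/filtered gene table.

    TE is the ratio of the replicate-averaged footprint RPKM to the mRNA
    RPKM.  It is left undefined (NaN) whenever any filter flag is set or the
    summed mRNA reads are below ``min_mrna_reads_te`` (at-least semantics:
    genes with exactly the floor are retained by this rule).
    """
    out = measurements.copy()
    blocked = out["flags"].astype(str).str.len() > 0
    low_mrna = out["mrna_reads_total"] < min_mrna_reads_te
    with np.errstate(divide="ignore", invalid="ignore"):
        te = out["fp_rpkm_mean"] / out["mrna_rpkm_mean"]
    te = te.where(~(blocked | low_mrna | (out["mrna_rpkm_mean"] <= 0)))
    out["te"] = te
    return out
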