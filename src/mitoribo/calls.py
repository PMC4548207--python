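"""Fold-threshold regulation calls and the cross-phase summary statistics.

Genes are classified between an ordered phase pair (A, B) on pure fold
cutoffs: an mRNA-level change requires the RPKM ratio to exceed a threshold
(default 3x, strict), and a translation-efficiency (TE) change requires
*both* a >3x TE ratio and a >2x footprint-RPKM ratio in the same direction —
the dual threshold that makes a TE change biologically meaningful only when
the absolute amount of synthesis on the mRNA changes too.  No shrinkage or
hypothesis testing is applied; the fold cutoff is justified against the
replicate standard deviation reported by :func:`replicate_qc`.

Fold ratios are computed on replicate-averaged linear-scale RPKM/TE;
correlations are computed on log2 folds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import PHASES

MRNA_CLASSES = ("up", "down", "unchanged", "filtered")
TE_CLASSES = ("repressed", "activated", "unchanged", "filtered")


def _pivot(measurements: pd.DataFrame, column: str) -> pd.DataFrame:
    return measurements.pivot_table(
        index="gene", columns="phase", values=column, aggfunc="first", dropna=False
    )


def _check_phases(measurements: pd.DataFrame, phase_a: str, phase_b: str) -> None:
    present = set(measurements["phase"].unique())
    for p in (phase_a, phase_b):
        if p not in present:
            raise ValueError(f"phase {p!r} not present in measurements")


def call_mrna_regulation(
    measurements: pd.DataFrame, phase_a: str, phase_b: str, fold: float = 3.0
) -> pd.DataFrame:
    """Classify mRNA-level changes of B relative to A.

    ``down`` iff RPKM(A)/RPKM(B) strictly exceeds ``fold``; ``up`` iff the
    inverse ratio does; boundary equality is ``unchanged``.  Genes carrying
    any mRNA filter flag (or missing) in either phase are ``filtered``.
    Returns a frame indexed by gene with ``mrna_fold`` (= RPKM(A)/RPKM(B))
    and ``mrna_class``; the phase pair is recorded in plain columns.
    """
    _check_phases(measurements, phase_a, phase_b)
    m = measurements.copy()
    flags = m["flags"].astype(str)
    m["mrna_ok"] = ~(
        flags.str.contains("low_reads_mrna")
        | flags.str.contains("replicate_discordant_mrna")
    )
    rpkm = _pivot(m, "mrna_rpkm_mean")
    ok = _pivot(m, "mrna_ok").fillna(False).astype(bool)
    a, b = rpkm[phase_a], rpkm[phase_b]
    defined = ok[phase_a] & ok[phase_b] & (a > 0) & (b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    cls = pd.Series("filtered", index=rpkm.index, dtype=object)
    cls[defined] = "unchanged"
    cls[defined & (ratio > fold)] = "down"
    cls[defined & (ratio < 1.0 / fold)] = "up"
    return pd.DataFrame(
        {
            "phase_a": phase_a,
            "phase_b": phase_b,
            "mrna_fold": ratio.where(defined),
            "mrna_class": cls,
        }
    )


def call_te_regulation(
    measurements: pd.DataFrame,
    phase_a: str,
    phase_b: str,
    te_fold: float = 3.0,
    fp_fold: float = 2.0,
) -> pd.DataFrame:
    """Classify TE changes of B relative to A under the dual threshold.

    ``repressed`` (in B) iff TE(A)/TE(B) > ``te_fold`` AND
    FP-RPKM(A)/FP-RPKM(B) > ``fp_fold``; ``activated`` symmetric with both
    inverse ratios.  Genes with undefined TE in either phase are
    ``filtered``.  Returns a frame indexed by gene with ``te_fold``,
    ``fp_fold`` (both A/B ratios) and ``te_class``.
    """
    _check_phases(measurements, phase_a, phase_b)
    te = _pivot(measurements, "te")
    fp = _pivot(measurements, "fp_rpkm_mean")
    te_a, te_b = te[phase_a], te[phase_b]
    fp_a, fp_b = fp[phase_a], fp[phase_b]
    defined = te_a.notna() & te_b.notna() & (te_b > 0) & (fp_b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        te_ratio = te_a / te_b
        fp_ratio = fp_a / fp_b
    cls = pd.Series("filtered", index=te.index, dtype=object)
    cls[defined] = "unchanged"
    cls[defined & (te_ratio > te_fold) & (fp_ratio > fp_fold)] = "repressed"
    cls[defined & (te_ratio < 1.0 / te_fold) & (fp_ratio < 1.0 / fp_fold)] = "activated"
    return pd.DataFrame(
        {
            "phase_a": phase_a,
            "phase_b": phase_b,
            "te_fold": te_ratio.where(defined),
            "fp_fold": fp_ratio.where(defined),
            "te_class": cls,
        }
    )


def call_regulation(
    measurements: pd.DataFrame,
    phase_a: str,
    phase_b: str,
    mrna_fold: float = 3.0,
    te_fold: float = 3.0,
    fp_fold: float = 2.0,
) -> pd.DataFrame:
    """Joint mRNA + TE call table for one ordered phase pair."""
    m = call_mrna_regulation(measurements, phase_a, phase_b, fold=mrna_fold)
    t = call_te_regulation(measurements, phase_a, phase_b, te_fold=te_fold, fp_fold=fp_fold)
    return pd.concat([m, t.drop(columns=["phase_a", "phase_b"])], axis=1)


_DOWN_LIKE = {"down", "repressed"}
_UP_LIKE = {"up", "activated"}


def overlap_fraction(
    primary_calls: pd.DataFrame,
    secondary_calls: pd.DataFrame,
    primary_class: str,
    quantity: str = "te",
    secondary_fold: float = 2.0,
) -> float | None:
    """Fraction of a primary call set concordant in a second comparison.

    Among genes carrying ``primary_class`` (e.g. ``"repressed"`` or
    ``"up"``) in ``primary_calls``, the fraction whose fold ratio for
    ``quantity`` (``"te"``, ``"mrna"`` or ``"fp"``) in ``secondary_calls``
    exceeds ``secondary_fold`` in the same direction.  Genes without a
    defined fold in the secondary comparison are excluded from the
    denominator (percentages are over classified genes).  Returns ``None``
    when the denominator is empty.
    """
    col = {"te": "te_fold", "mrna": "mrna_fold", "fp": "fp_fold"}[quantity]
    cls_col = "te_class" if primary_class in TE_CLASSES else "mrna_class"
    genes = primary_calls.index[primary_calls[cls_col] == primary_class]
    folds = secondary_calls[col].reindex(genes).dropna()
    if folds.empty:
        return None
    if primary_class in _DOWN_LIKE:
        concordant = folds > secondary_fold
    elif primary_class in _UP_LIKE:
        concordant = folds < 1.0 / secondary_fold
    else:
        raise ValueError(f"primary_class {primary_class!r} has no direction")
    return float(concordant.mean())


def fold_correlation(
    calls_ab: pd.DataFrame,
    calls_cb: pd.DataFrame,
    gene_subset=None,
    quantity: str = "te",
) -> tuple[pd.DataFrame, float | None]:
    """Pair log2 folds of two comparisons and report their Pearson r.

    Returns ``(pairs, r)`` where ``pairs`` has columns ``log2_fold_1`` and
    ``log2_fold_2`` over the genes defined in both; ``r`` is ``None`` when
    fewer than 3 genes remain.
    """
    col = {"te": "te_fold", "mrna": "mrna_fold", "fp": "fp_fold"}[quantity]
    f1, f2 = calls_ab[col], calls_cb[col]
    genes = f1.index.intersection(f2.index)
    if gene_subset is not None:
        genes = genes.intersection(pd.Index(gene_subset))
    pairs = pd.DataFrame(
        {"log2_fold_1": np.log2(f1.reindex(genes)), "log2_fold_2": np.log2(f2.reindex(genes))}
    ).dropna()
    if len(pairs) < 3:
        return pairs, None
    r = stats.pearsonr(pairs["log2_fold_1"], pairs["log2_fold_2"]).statistic
    return pairs, float(r)


def gene_set_medians(
    measurements: pd.DataFrame, gene_set, quantity: str = "te"
) -> pd.Series:
    """Per-phase median RPKM or TE over a gene set (e.g. a repressed set)."""
    genes = pd.Index(gene_set)
    if genes.empty:
        raise ValueError("gene set is empty")
    col = {
        "te": "te",
        "rpkm": "mrna_rpkm_mean",
        "mrna": "mrna_rpkm_mean",
        "fp": "fp_rpkm_mean",
    }[quantity]
    sub = measurements[measurements["gene"].isin(genes)]
    med = sub.groupby("phase")[col].median()
    return med.reindex([p for p in PHASES if p in med.index])


def fp_only_comparison(
    measurements: pd.DataFrame, phase_a: str, phase_b: str
) -> pd.DataFrame:
    """Footprint-RPKM fold table, no TE (for poly(A)-minus genes, e.g. histones).

    Genes must pass the FP filters and have positive FP density in both
    phases; anything else is excluded (and counted in the log).  Returns a
    frame indexed by gene with ``fp_rpkm_a``, ``fp_rpkm_b`` and ``fp_fold``
    (= A/B).
    """
    _check_phases(measurements, phase_a, phase_b)
    m = measurements.copy()
    flags = m["flags"].astype(str)
    m["fp_ok"] = ~(
        flags.str.contains("low_reads_fp") | flags.str.contains("replicate_discordant_fp")
    )
    fp = _pivot(m, "fp_rpkm_mean")
    ok = _pivot(m, "fp_ok").fillna(False).astype(bool)
    a, b = fp[phase_a], fp[phase_b]
    defined = ok[phase_a] & ok[phase_b] & (a > 0) & (b > 0)
    n_dropped = int((~defined).sum())
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "fp_only_comparison: %d genes excluded (filtered or zero FP)", n_dropped
        )
    out = pd.DataFrame(
        {"fp_rpkm_a": a[defined], "fp_rpkm_b": b[defined], "fp_fold": a[defined] / b[defined]}
    )
    return out


def replicate_qc(
    expression: pd.DataFrame, min_reads: int = 200, min_genes: int = 10
) -> pd.DataFrame:
    """Replicate reproducibility per sample: log-scale R^2 and ratio SD.

    For every phase x library the genes with more than ``min_reads`` summed
    reads and nonzero RPKM in both replicates are used to compute the R^2 of
    log2 replicate RPKMs, the standard deviation of log2(rep1/rep2), and the
    fold change corresponding to six of those standard deviations — the
    yardstick against which a 3-fold call cutoff can be judged.  Refuses
    (raises) when fewer than ``min_genes`` genes survive.
    """
    rows = []
    for (phase, library), sample in expression.groupby(["phase", "library"], sort=False):
        reps = sample.pivot_table(index="gene", columns="replicate", values="rpkm")
        total = sample.groupby("gene")["reads"].sum()
        keep = (total > min_reads).reindex(reps.index, fill_value=False)
        reps = reps.loc[keep & (reps > 0).all(axis=1)]
        if len(reps) < min_genes:
            raise ValueError(
                f"replicate QC refused for {phase}/{library}: only {len(reps)} "
                f"surviving genes (< {min_genes})"
            )
        l1, l2 = np.log2(reps.iloc[:, 0]), np.log2(reps.iloc[:, 1])
        if np.isclose(l1.std(), 0) or np.isclose(l2.std(), 0):
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(l1, l2)[0, 1] ** 2)
        sd = float((l1 - l2).std(ddof=1))
        rows.append(
            {
                "phase": phase,
                "library": library,
                "n_genes": len(reps),
                "r_squared": r2,
                "sd_log2_ratio": sd,
                "fold_at_6sd": float(2.0 ** (6.0 * sd)),
            }
        )
    return pd.DataFrame(rows)
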