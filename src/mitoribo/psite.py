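"""P-site assignment and RPKM densities for ribosome footprints.

Footprint alignments arrive as (transcript, 5'-end position, read length)
records.  Because the distance from a footprint's 5' end to the ribosomal
P-site depends on the exact nuclease trimming, the offset is calibrated per
read length from the metagene pile-up at the start of coding sequences (and
cross-checked at the stop codon).  Reads are then counted for a gene only
when their inferred P-site falls inside the CDS, and densities are expressed
as RPKM (reads per kilobase of feature per million mapped reads).
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """No read length reached the minimum evidence for offset calibration."""


def trim_3prime(read_sequence: str, linker_sequence: str) -> str:
    """Remove the 3' linker and any trailing poly(A) run from a raw read.

    The linker is searched 5'->3' as an exact match; everything from its
    first occurrence onward is discarded.  If the linker is absent (e.g. the
    read ended inside a poly(A) stretch) any trailing run of ``A`` is
    stripped instead.  An empty read yields an empty string.
    """
    if linker_sequence:
        hit = read_sequence.find(linker_sequence)
        if hit >= 0:
            return read_sequence[:hit]
    return read_sequence.rstrip("A")


def _mode_smallest(values: np.ndarray) -> int:
    """Mode of an integer array; ties broken toward the smallest value."""
    counts = Counter(values.tolist())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return int(best[0])


def calibrate_psite_offsets(
    alignments: pd.DataFrame,
    transcriptome: pd.DataFrame,
    min_reads_per_length: int = 100,
    window: int | None = None,
    check_stop: bool = True,
) -> dict[int, int]:
    """Calibrate per-read-length P-site offsets from start-codon pile-ups.

    For each read length L the candidate offsets are the distances
    ``cds_start - five_prime_pos`` over reads whose 5' end lies within a
    window upstream of the start codon (default: one read length).  The
    initiation-site enrichment makes the true offset the modal distance;
    ties go to the smallest offset.  Lengths with fewer than
    ``min_reads_per_length`` reads in the window are omitted; if no length
    qualifies a :class:`CalibrationError` is raised.

    When ``check_stop`` is set the same procedure is run against the last
    CDS codon and any disagreement is logged as a warning (the start-codon
    estimate is always the one returned).
    """
    cds_start = transcriptome["cds_start"]
    cds_end = transcriptome["cds_end"]
    start = cds_start.reindex(alignments["transcript_id"]).to_numpy()
    last_codon = (cds_end.reindex(alignments["transcript_id"]).to_numpy()) - 3
    five = alignments["five_prime_pos"].to_numpy()
    rlen = alignments["read_length"].to_numpy()

    offsets: dict[int, int] = {}
    for length in sorted(np.unique(rlen)):
        sel = rlen == length
        win = int(window) if window is not None else int(length)
        d_start = start[sel] - five[sel]
        cand = d_start[(d_start > 0) & (d_start <= win)]
        if len(cand) < min_reads_per_length:
            logger.info(
                "read length %d: %d reads in start window < %d, omitted",
                length,
                len(cand),
                min_reads_per_length,
            )
            continue
        offset = _mode_smallest(cand)
        offsets[int(length)] = offset
        if check_stop:
            d_stop = last_codon[sel] - five[sel]
            cand_stop = d_stop[(d_stop > 0) & (d_stop <= win)]
            if len(cand_stop) >= min_reads_per_length:
                stop_offset = _mode_smallest(cand_stop)
                if stop_offset != offset:
                    logger.warning(
                        "read length %d: stop-codon offset %d disagrees with "
                        "start-codon offset %d; using start-codon estimate",
                        length,
                        stop_offset,
                        offset,
                    )
    if not offsets:
        raise CalibrationError(
            f"no read length reached {min_reads_per_length} reads in the "
            "calibration window"
        )
    return offsets


def assign_psites(
    alignments: pd.DataFrame,
    offsets: dict[int, int],
    transcriptome: pd.DataFrame,
) -> pd.Series:
    """Count CDS-restricted P-sites per gene.

    Each read's P-site is ``five_prime_pos + offset[read_length]``; the read
    is counted for its transcript iff the P-site falls in
    ``[cds_start, cds_end)``.  Reads of uncalibrated lengths and reads whose
    P-site lands outside the CDS are dropped (the counts are logged, not
    fatal).  Returns a Series over all transcriptome genes (zeros included).
    """
    rlen = alignments["read_length"].to_numpy()
    known = np.isin(rlen, list(offsets))
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("dropped %d reads with uncalibrated lengths", n_unknown)
    sub = alignments.loc[known]
    off = sub["read_length"].map(offsets).to_numpy()
    psite = sub["five_prime_pos"].to_numpy() + off
    tx = sub["transcript_id"]
    cds_start = transcriptome["cds_start"].reindex(tx).to_numpy()
    cds_end = transcriptome["cds_end"].reindex(tx).to_numpy()
    in_cds = (psite >= cds_start) & (psite < cds_end)
    n_outside = int((~in_cds).sum())
    if n_outside:
        logger.info("dropped %d reads with P-sites outside the CDS", n_outside)
    counted = tx.loc[in_cds]
    counts = counted.value_counts()
    return (
        counts.reindex(transcriptome.index, fill_value=0)
        .rename("reads")
        .rename_axis("gene")
        .astype(int)
    )


def compute_rpkm(
    counts: pd.Series | np.ndarray,
    feature_length: pd.Series | np.ndarray,
    total_mapped_reads: float,
) -> pd.Series | np.ndarray:
    """Reads per kilobase of feature per million mapped reads.

    ``rpkm = counts / (feature_length/1e3) / (total_mapped_reads/1e6)``.
    The feature length is the CDS for footprint samples and the full
    transcript for mRNA samples (densities are per-feature, so a gene with
    zero reads has RPKM exactly zero).
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    length = np.asarray(feature_length, dtype=float)
    if (length <= 0).any():
        raise ValueError("feature lengths must be > 0")
    return counts / (length / 1e3) / (total_mapped_reads / 1e6)


def add_rpkm(
    counts: pd.DataFrame,
    transcriptome: pd.DataFrame,
    total_reads: dict | None = None,
) -> pd.DataFrame:
    """Attach an ``rpkm`` column to a tidy count table.

    ``counts`` has columns ``gene, phase, replicate, library, reads``.  The
    per-sample total defaults to the sum of that sample's counts (all mapped
    reads counted); pass ``total_reads`` keyed by ``(phase, replicate,
    library)`` to override, e.g. when only a subset of mapped reads is
    tabulated.  FP densities use CDS length, mRNA densities transcript
    length.
    """
    cds_len = (transcriptome["cds_end"] - transcriptome["cds_start"]).rename("flen")
    tx_len = transcriptome["length"].rename("flen")
    out = counts.copy()
    flen = np.where(
        out["library"].to_numpy() == "FP",
        cds_len.reindex(out["gene"]).to_numpy(),
        tx_len.reindex(out["gene"]).to_numpy(),
    )
    key = ["phase", "replicate", "library"]
    if total_reads is None:
        totals = out.groupby(key)["reads"].transform("sum").to_numpy(dtype=float)
    else:
        totals = np.array(
            [total_reads[k] for k in zip(out["phase"], out["replicate"], out["library"])],
            dtype=float,
        )
    out["rpkm"] = out["reads"] / (flen / 1e3) / (totals / 1e6)
    return out
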