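"""On-disk formats: BED6 alignments, annotation sidecar, TSV tables, YAML config.

Conventions: all coordinates are 0-based half-open (BED); TSV tables carry
'#'-prefixed header comments naming the units of each quantity (reads, RPKM,
dimensionless TE, rates per hour); trace times are minutes.  Readers validate
coordinates and report the offending line number on malformed input.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""


# ---------------------------------------------------------------- annotation

def write_annotation(transcriptome: pd.DataFrame, bed_path, sidecar_path) -> None:
    """Write the transcript annotation: CDS intervals as BED6 plus a TSV
    sidecar with transcript length and CDS bounds (the authoritative file
    for round-tripping)."""
    with open(bed_path, "w") as fh:
        for tid, row in transcriptome.iterrows():
            fh.write(
                f"{tid}\t{int(row.cds_start)}\t{int(row.cds_end)}\t{tid}\t0\t+\n"
            )
    with open(sidecar_path, "w") as fh:
        fh.write("# transcript annotation: 0-based half-open coordinates, nt\n")
        transcriptome.reset_index().to_csv(fh, sep="\t", index=False)


def read_annotation(sidecar_path) -> pd.DataFrame:
    """Read the annotation sidecar; validates CDS bounds per line."""
    df = pd.read_csv(sidecar_path, sep="\t", comment="#")
    required = {"transcript_id", "length", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{sidecar_path}: missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not (0 <= row.cds_start < row.cds_end <= row.length):
            raise ParseError(
                f"{sidecar_path}:{i}: invalid CDS bounds "
                f"[{row.cds_start}, {row.cds_end}) on length {row.length}"
            )
    return df.set_index("transcript_id")


# ---------------------------------------------------------------- alignments

def write_alignments(alignments: pd.DataFrame, path) -> None:
    """Write alignments as BED6; the read length is encoded in the name
    field (``len=<nt>``), adjacent to the (unused) score column."""
    with open(path, "w") as fh:
        for row in alignments.itertuples(index=False):
            start = int(row.five_prime_pos)
            fh.write(
                f"{row.transcript_id}\t{start}\t{start + int(row.read_length)}"
                f"\tlen={int(row.read_length)}\t0\t+\n"
            )


def read_alignments(path, transcriptome: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read BED6 alignments; validates coordinates (and transcript bounds
    when an annotation is supplied)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED fields")
            tid, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            length = end - start
            if name.startswith("len="):
                declared = int(name[4:])
                if declared != length:
                    raise ParseError(
                        f"{path}:{lineno}: name declares length {declared} "
                        f"but interval spans {length}"
                    )
            if transcriptome is not None:
                if tid not in transcriptome.index:
                    raise ParseError(f"{path}:{lineno}: unknown transcript {tid!r}")
                if end > int(transcriptome.at[tid, "length"]):
                    raise ParseError(
                        f"{path}:{lineno}: read extends beyond transcript {tid!r}"
                    )
            records.append((tid, start, length))
    return pd.DataFrame(
        records, columns=["transcript_id", "five_prime_pos", "read_length"]
    )


# -------------------------------------------------------------------- tables

#: unit annotations written above each table kind
_TABLE_UNITS = {
    "counts": "reads: raw read counts; rpkm: reads per kilobase per million",
    "measurements": (
        "reads_total: reads summed over replicates; rpkm: reads per kilobase "
        "per million (replicate mean); te: dimensionless FP/mRNA density ratio"
    ),
    "calls": "folds: linear-scale ratios phase_a/phase_b (dimensionless)",
    "truth": "mrna_*: relative abundance (arbitrary units); te_*: dimensionless",
    "rates": "rate_per_hour: GFP/mCherry ratio change per hour",
    "qc": "sd_log2_ratio: SD of log2(rep1/rep2); fold_at_6sd: 2^(6*SD)",
    "generic": "see column names",
}


def write_table(df: pd.DataFrame, path, kind: str = "generic", index: bool = False) -> None:
    """Write a TSV with a '#'-prefixed header naming the units."""
    with open(path, "w") as fh:
        fh.write(f"# mitoribo {kind} table\n")
        fh.write(f"# units: {_TABLE_UNITS.get(kind, _TABLE_UNITS['generic'])}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, index_col=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_traces(traces: pd.DataFrame, path) -> None:
    """Per-cell fluorescence traces as CSV (times in minutes, a.u. signals)."""
    traces.to_csv(path, index=False, float_format="%.10g")


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "time_min", "gfp", "mcherry"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing trace columns {sorted(missing)}")
    return df


# -------------------------------------------------------------------- config

def write_config(config, path) -> None:
    """Serialise a (data)class config to YAML."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    def plain(v):
        if isinstance(v, dict):
            return {k: plain(x) for k, x in v.items()}
        if isinstance(v, (tuple, list)):
            return [plain(x) for x in v]
        return v

    payload = {k: plain(v) for k, v in payload.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data
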