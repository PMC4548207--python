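"""End-to-end driver: simulation -> calibration -> quantification -> TE -> calls.

Every intermediate table is written to the output directory together with a
run manifest (versions, seed, thresholds, per-stage gene and read counts).
Given an identical configuration the run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, calls as calls_mod, io as mio, psite, te as te_mod
from .simulate import (
    PHASES,
    SimulationConfig,
    generate_transcriptome,
    simulate_counts,
    simulate_expression,
    simulate_footprint_positions,
)

#: ordered phase pairs analysed by default (A, B); folds are A/B
COMPARISONS: tuple[tuple[str, str], ...] = (("G2", "M"), ("G2", "G1"), ("G1", "M"))


@dataclass
class PipelineConfig:
    """Everything a full run needs: simulation settings, thresholds, paths."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_reads: int = 200
    max_replicate_fold: float = 3.0
    te_fold: float = 3.0
    fp_fold: float = 2.0
    mrna_fold: float = 3.0
    min_mrna_reads_te: int = 200
    calibration_reads: int = 200_000
    outdir: str | Path = "mitoribo_run"

    def __post_init__(self) -> None:
        for name in ("max_replicate_fold", "te_fold", "fp_fold", "mrna_fold"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1 (multiplicative threshold)")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline and write all outputs.

    Returns a result bundle with the in-memory tables and the manifest.
    Stages: transcriptome -> planted truth -> footprint positions &
    P-site-offset calibration -> counts -> RPKM -> replicate merge/filter ->
    TE -> regulation calls per phase pair -> summaries and replicate QC.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    manifest: dict = {
        "package": "mitoribo",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": sim.seed,
        "thresholds": {
            "min_reads": config.min_reads,
            "max_replicate_fold": config.max_replicate_fold,
            "te_fold": config.te_fold,
            "fp_fold": config.fp_fold,
            "mrna_fold": config.mrna_fold,
            "min_mrna_reads_te": config.min_mrna_reads_te,
        },
        "stages": {},
    }

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # surface the failing stage
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    transcriptome = stage("transcriptome", generate_transcriptome, sim)
    mio.write_annotation(transcriptome, out / "annotation.bed", out / "annotation.tsv")
    manifest["stages"]["transcriptome"] = {"n_genes": int(len(transcriptome))}

    truth = stage("expression", simulate_expression, sim, transcriptome)
    mio.write_table(truth.reset_index(), out / "ground_truth.tsv", kind="truth")
    manifest["stages"]["expression"] = {
        "planted": truth["label"].value_counts().to_dict()
    }

    positions = stage(
        "positions",
        simulate_footprint_positions,
        truth,
        transcriptome,
        sim,
        n_reads=config.calibration_reads,
    )
    mio.write_alignments(positions, out / "calibration_footprints.bed")
    offsets = stage(
        "calibrate", psite.calibrate_psite_offsets, positions, transcriptome
    )
    manifest["stages"]["calibration"] = {
        "n_reads": int(len(positions)),
        "offsets": {str(k): int(v) for k, v in sorted(offsets.items())},
    }
    psite_counts = stage("quantify", psite.assign_psites, positions, offsets, transcriptome)
    mio.write_table(
        psite_counts.reset_index(), out / "calibration_psite_counts.tsv", kind="counts"
    )
    manifest["stages"]["quantify"] = {"psite_reads_counted": int(psite_counts.sum())}

    counts = stage("counts", simulate_counts, truth, transcriptome, sim)
    expression = stage("rpkm", psite.add_rpkm, counts, transcriptome)
    mio.write_table(expression, out / "expression.tsv", kind="counts")
    manifest["stages"]["counts"] = {
        "n_samples": int(expression.groupby(["phase", "replicate", "library"]).ngroups),
        "reads_per_sample": {
            f"{p}/rep{r}/{l}": int(n)
            for (p, r, l), n in expression.groupby(["phase", "replicate", "library"])[
                "reads"
            ].sum().items()
        },
    }

    measurements = stage(
        "merge_filter",
        te_mod.merge_and_filter,
        expression,
        min_reads=config.min_reads,
        max_replicate_fold=config.max_replicate_fold,
        n_replicates=sim.n_replicates,
    )
    measurements = stage(
        "te", te_mod.compute_te, measurements, min_mrna_reads_te=config.min_mrna_reads_te
    )
    mio.write_table(measurements, out / "gene_measurements.tsv", kind="measurements")
    manifest["stages"]["filtering"] = {
        phase: {
            "n_genes": int((measurements["phase"] == phase).sum()),
            "n_unflagged": int(
                (
                    (measurements["phase"] == phase)
                    & (measurements["flags"].astype(str) == "")
                ).sum()
            ),
            "n_te_defined": int(
                ((measurements["phase"] == phase) & measurements["te"].notna()).sum()
            ),
        }
        for phase in PHASES
    }

    call_frames = []
    summary_rows = []
    for a, b in COMPARISONS:
        c = stage(
            f"call_{a}_vs_{b}",
            calls_mod.call_regulation,
            measurements,
            a,
            b,
            mrna_fold=config.mrna_fold,
            te_fold=config.te_fold,
            fp_fold=config.fp_fold,
        )
        call_frames.append(c.reset_index())
        summary_rows.append(
            {
                "phase_a": a,
                "phase_b": b,
                "mrna_down_in_b": int((c["mrna_class"] == "down").sum()),
                "mrna_up_in_b": int((c["mrna_class"] == "up").sum()),
                "te_repressed_in_b": int((c["te_class"] == "repressed").sum()),
                "te_activated_in_b": int((c["te_class"] == "activated").sum()),
                "n_mrna_classified": int((c["mrna_class"] != "filtered").sum()),
                "n_te_classified": int((c["te_class"] != "filtered").sum()),
            }
        )
    all_calls = pd.concat(call_frames, ignore_index=True)
    summary = pd.DataFrame(summary_rows)
    mio.write_table(all_calls, out / "regulation_calls.tsv", kind="calls")
    mio.write_table(summary, out / "call_summary.tsv", kind="calls")
    manifest["stages"]["calls"] = {
        f"{r['phase_a']}_vs_{r['phase_b']}": {
            k: r[k] for k in r.index if k not in ("phase_a", "phase_b")
        }
        for _, r in summary.iterrows()
    }

    qc = stage("qc", calls_mod.replicate_qc, expression, min_reads=config.min_reads)
    mio.write_table(qc, out / "replicate_qc.tsv", kind="qc")

    mio.write_config(_config_payload(config), out / "run_config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "transcriptome": transcriptome,
        "truth": truth,
        "offsets": offsets,
        "expression": expression,
        "measurements": measurements,
        "calls": all_calls,
        "summary": summary,
        "qc": qc,
        "manifest": manifest,
    }


def _config_payload(config: PipelineConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["outdir"] = str(payload["outdir"])
    payload["sim"]["psite_offsets"] = {
        int(k): int(v) for k, v in payload["sim"]["psite_offsets"].items()
    }
    return payload
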