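"""End-to-end orchestration: images -> quantification -> records -> analytics.

Every output directory receives a provenance JSON (inputs, config hash,
package version, seeds) sufficient to re-execute the stage; outputs are
deterministic for fixed seeds.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .imaging import ThresholdPolicy, quantify_run, segment_run
from .io import PipelineConfig, read_run, write_records_csv
from .kinetics import FibreCriteria, ScoreRubric, record_from_run
from .registry import Condition, ParameterRecord

__all__ = ["run_pipeline", "quantify_manifests", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and run id."""

    def __init__(self, stage: str, run_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for run {run_id!r}: {cause}")
        self.stage = stage
        self.run_id = run_id


def _provenance(outdir: Path, config: PipelineConfig, inputs: list[str]) -> None:
    blob = {
        "package": "thromboflow",
        "version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
        "config_hash": config.hash,
        "inputs": inputs,
        "seed": config.seed,
    }
    (outdir / "provenance.json").write_text(json.dumps(blob, indent=2, sort_keys=True))


def quantify_manifests(
    manifest_paths: list[str | Path],
    config: PipelineConfig,
    outdir: str | Path,
) -> list[ParameterRecord]:
    """Quantify stored runs into parameter records (with provenance)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    policy = ThresholdPolicy(k_t0=config.k_t0, k_t0_fibrin=config.k_t0_fibrin)
    rubric = ScoreRubric()
    criteria = FibreCriteria(
        min_skeleton_px=config.fibre_min_skeleton_px,
        min_elongation=config.fibre_min_elongation,
    )
    records = []
    for path in manifest_paths:
        path = Path(path)
        run_id = path.parent.name
        try:
            run = read_run(path)
        except Exception as exc:
            raise StageError("read", run_id, exc) from exc
        try:
            manifest = json.loads(path.read_text())
            condition = Condition(**manifest.get("condition", {}) or {})
            masks = segment_run(
                run, config.low_period_px, config.high_period_px, policy,
                config.clean_radius_px, qc=config.qc_enabled,
            )
            quant = quantify_run(
                run, config.low_period_px, config.high_period_px, policy,
                config.clean_radius_px, qc=config.qc_enabled,
            )
            record = record_from_run(
                run, masks, quant,
                subject=manifest.get("subject", "S1"),
                surface=manifest.get("surface") or "M6",
                condition=condition, rubric=rubric, criteria=criteria,
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("quantify", run_id, exc) from exc
        records.append(record)
    write_records_csv(records, outdir / "records.csv")
    _provenance(outdir, config, [str(p) for p in manifest_paths])
    return records


def run_pipeline(
    manifest_paths: list[str | Path],
    config: PipelineConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Quantify runs, assemble records, and emit scaled heatmap tables.

    Returns a map of produced artifact names to paths.  Any stage failure
    aborts with the stage name and the offending run id.
    """
    from .cohort import scaled_cell_table
    from .synthetic import cohort_to_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = quantify_manifests(manifest_paths, config, outdir)
    frame = cohort_to_frame(records)
    try:
        scaled = scaled_cell_table(frame[["subject", "surface", "tf", "parameter",
                                          "time", "value"]])
        scaled.to_csv(outdir / "scaled.csv", index=False)
    except Exception as exc:
        raise StageError("scale", "-", exc) from exc
    artifacts = {
        "records": outdir / "records.csv",
        "scaled": outdir / "scaled.csv",
        "provenance": outdir / "provenance.json",
    }
    return artifacts
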