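"""Readers, writers, manifests and pipeline configuration.

Formats are deliberately plain: 8-bit TIFF stacks per channel with a JSON
manifest per run, masks as PNG, tidy tables as UTF-8 comma-separated CSV
with a header row and '.' decimal separator, configs and reports as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .registry import Condition, ParameterRecord

__all__ = [
    "RunManifest",
    "PipelineConfig",
    "write_run",
    "read_run",
    "write_records_csv",
    "read_records_csv",
    "read_csv_strict",
]


class InputError(ValueError):
    """Malformed input file or manifest."""


@dataclass
class RunManifest:
    """Description of one stored flow run: file paths and acquisition metadata."""

    run_id: str
    subject: str
    surface: str
    condition: dict
    channel_files: dict[str, str]  # channel -> TIFF path (relative to manifest)
    times_min: list[int]
    pixel_size_um: float
    bit_depth: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise InputError("bit depth must be 8 or 16")
        if sorted(self.times_min) != list(self.times_min):
            raise InputError("capture times must be sorted")

    def validate_files(self, base: Path) -> None:
        for channel, rel in self.channel_files.items():
            if not (base / rel).exists():
                raise InputError(f"missing file for channel {channel!r}: {rel}")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults; unknown keys rejected."""

    schema_version: int = 1
    # background suppression band (spatial periods, px)
    low_period_px: float = 200.0
    high_period_px: float = 3.0
    # t0-referenced thresholding
    k_t0: float = 3.0
    k_t0_fibrin: float = 5.0
    clean_radius_px: int = 3
    qc_enabled: bool = False
    qc_agreement_floor: float = 0.5
    qc_max_retries: int = 1
    # fibre criteria
    fibre_min_skeleton_px: int = 20
    fibre_min_elongation: float = 4.0
    # scaling / relevance
    scale_max: float = 10.0
    integrate_how: str = "sum"
    # prediction
    knn_k: int = 3
    roster_seed: int = 0
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @property
    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_run(run, truth, outdir: str | Path, subject: str = "S1") -> Path:
    """Write a run as per-channel TIFF stacks + manifest; ground truth (when
    given) as PNG masks and a CSV of true coverages.  Returns the manifest
    path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    channel_files = {}
    for channel in run.channels:
        stack = np.stack([run.frames[channel][t] for t in run.times])
        rel = f"{channel}.tif"
        tifffile.imwrite(outdir / rel, stack)
        channel_files[channel] = rel
    manifest = RunManifest(
        run_id=outdir.name,
        subject=subject,
        surface="",
        condition={},
        channel_files=channel_files,
        times_min=list(run.times),
        pixel_size_um=run.pixel_size_um,
        bit_depth=8,
        seed=run.seed,
    )
    (outdir / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    if truth is not None:
        gt_dir = outdir / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        rows = []
        for channel, per_time in truth.masks.items():
            for t, mask in per_time.items():
                iio.imwrite(
                    gt_dir / f"{channel}_t{t}.png",
                    (mask.astype(np.uint8) * 255),
                )
                rows.append(
                    {"channel": channel, "time": t, "true_sac": truth.sac[channel][t]}
                )
        pd.DataFrame(rows).to_csv(gt_dir / "true_sac.csv", index=False)
    return outdir / "manifest.json"


def read_run(manifest_path: str | Path):
    """Load a stored run back into a FlowRunImages object."""
    from .synthetic import FlowRunImages

    manifest_path = Path(manifest_path)
    try:
        raw = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"malformed manifest {manifest_path}: {exc}") from exc
    manifest = RunManifest(**raw)
    base = manifest_path.parent
    manifest.validate_files(base)
    frames: dict[str, dict[int, np.ndarray]] = {}
    for channel, rel in manifest.channel_files.items():
        stack = tifffile.imread(base / rel)
        frames[channel] = {t: stack[i] for i, t in enumerate(manifest.times_min)}
    return FlowRunImages(
        frames=frames,
        times=tuple(manifest.times_min),
        channels=tuple(manifest.channel_files),
        pixel_size_um=manifest.pixel_size_um,
        seed=manifest.seed or 0,
    )


def write_records_csv(records: list[ParameterRecord], path: str | Path) -> None:
    """Write parameter records as a tidy CSV (one value per row)."""
    from .synthetic import cohort_to_frame

    # %.17g guarantees binary round-trip of float64 values
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_records_csv(path: str | Path) -> list[ParameterRecord]:
    """Read a tidy record CSV back into ParameterRecord objects."""
    frame = read_csv_strict(path)
    records = []
    group_cols = ["subject", "surface", "shear_rate", "tf", "tf_dose_pm", "ifviia",
                  "cti", "soluble"]
    for key, grp in frame.groupby(group_cols, sort=True):
        (subject, surface, shear, tf, dose, ifviia, cti, soluble) = key
        condition = Condition(
            shear_rate=int(shear), tf=bool(tf), tf_dose_pm=float(dose),
            ifviia=bool(ifviia), cti=bool(cti), soluble=str(soluble),
        )
        values = {}
        p9 = None
        for _, row in grp.iterrows():
            if row["parameter"] == "P9":
                p9 = float(row["value"])
            else:
                values[(row["parameter"], int(row["time"]))] = float(row["value"])
        provenance = str(grp["provenance"].iloc[0]) if "provenance" in grp else "measured"
        records.append(
            ParameterRecord(
                subject=str(subject), surface=str(surface), condition=condition,
                values=values, p9=p9, provenance=provenance,
            )
        )
    return records


def read_csv_strict(path: str | Path) -> pd.DataFrame:
    """Read a CSV in the fixed dialect (UTF-8, comma, '.' decimal, header).

    Decimal commas (``"1,23"`` inside a quoted numeric field) are rejected
    with an explicit dialect error naming the offending column.
    """
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if "value" in frame.columns and frame["value"].dtype == object:
        bad = frame["value"].astype(str).str.fullmatch(r"-?\d+,\d+")
        if bad.any():
            line = int(frame.index[bad][0]) + 2
            raise InputError(
                f"{path}: decimal comma in column 'value' near line {line}; "
                "the CSV dialect requires '.' decimals"
            )
    return frame
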