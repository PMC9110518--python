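"""End-to-end commands: quantify one lesion, analyse a cohort.

These functions are the programmatic face of the CLI.  Every output
directory receives a ``provenance.json`` sufficient to re-run the
command (config echo, seed, package version, threshold estimate).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .errors import FormatError, InputError
from .metrics import compute_ratio_metrics, compute_voi_metrics, metrics_row
from .segmentation import SeedRegion, ThresholdParams, define_control_voi, segment_lesion_voi
from .stats import (
    DEFAULT_METRICS,
    cohort_long_format,
    report_to_frame,
    report_to_markdown,
    stage_comparison_report,
    validate_cohort,
)
from .suv import compute_suv_map
from .volumes import UNITS_ACTIVITY, load_acquisition_meta, read_volume

logger = logging.getLogger(__name__)

#: columns every per-lesion metrics CSV carries
METRICS_COLUMNS = (
    "patient_id",
    "lesion_id",
    "stage",
    "suv_max",
    "suv_mean",
    "mbv_cm3",
    "tbu",
    "rsuv_max",
    "rsuv_mean",
    "rtbu",
)


@dataclass
class RunConfig:
    """Configuration of one quantification run."""

    volume_path: str
    meta_path: str
    lesion_region: SeedRegion
    control_region: SeedRegion
    output_dir: str
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    suv_percent: bool = True
    lesion_id: str = "L1"
    stage: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_provenance(out_dir: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["bonequant_version"] = __version__
    (out_dir / "provenance.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
    )


def load_regions(path: str | Path) -> list[SeedRegion]:
    """Load one or more region definitions from a JSON file."""
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, dict):
        raw = [raw]
    return [SeedRegion.from_dict(d) for d in raw]


def run_quantify(config: RunConfig) -> pd.DataFrame:
    """Volume + sidecar + regions -> one per-lesion metrics CSV row.

    Writes ``metrics.csv`` and ``provenance.json`` into the output
    directory and returns the metrics table.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    volume = read_volume(config.volume_path, expected_units=UNITS_ACTIVITY)
    meta = load_acquisition_meta(config.meta_path)
    suv = compute_suv_map(volume, meta, percent=config.suv_percent)

    lesion_voi = segment_lesion_voi(suv, config.lesion_region, config.threshold)
    control_voi = define_control_voi(suv, config.control_region)
    lesion_m = compute_voi_metrics(suv, lesion_voi)
    control_m = compute_voi_metrics(suv, control_voi)
    ratios = compute_ratio_metrics(lesion_m, control_m)

    row = metrics_row(
        patient_id=meta.patient_id,
        lesion_id=config.lesion_id,
        stage=config.stage,
        lesion=lesion_m,
        ratios=ratios,
    )
    table = pd.DataFrame([row], columns=METRICS_COLUMNS)
    table.to_csv(out_dir / "metrics.csv", index=False)

    est = lesion_voi.threshold_used
    cfg = config.to_dict()
    _write_provenance(
        out_dir,
        {
            "command": "quantify",
            "config": cfg,
            "config_hash": _config_hash(cfg),
            "threshold_estimate": {
                "mode_value": est.mode_value,
                "base_value": est.base_value,
                "sd": est.sd,
                "threshold": est.threshold,
            },
        },
    )
    logger.info("quantified lesion %s: MBV=%.3f cm^3", config.lesion_id, lesion_m.mbv_cm3)
    return table


REQUIRED_COHORT_COLUMNS = ("patient_id", "lesion_id", "stage")


def load_cohort_table(csv_path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort CSV (one row per lesion).

    Requires ``patient_id``, ``lesion_id`` and ``stage`` columns; lesion
    ids must be unique; metric columns are optional.
    """
    csv_path = Path(csv_path)
    try:
        table = pd.read_csv(csv_path)
    except Exception as exc:
        raise FormatError(f"cannot parse cohort CSV {csv_path}: {exc}") from exc
    if table.empty:
        raise FormatError(f"{csv_path}: empty cohort table")
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{csv_path}: missing required column {col!r}")
    if table["stage"].isna().any():
        row = int(table.index[table["stage"].isna()][0])
        raise FormatError(f"{csv_path}: missing stage in row {row}")
    table["stage"] = table["stage"].astype(int)
    try:
        validate_cohort(table)
    except InputError as exc:
        raise FormatError(f"{csv_path}: {exc}") from exc
    return table


def reference_cohort() -> pd.DataFrame:
    """The packaged reference cohort table: 23 mandibular ARONJ lesions
    across 21 patients with clinical stages 1-3."""
    with resources.as_file(
        resources.files("bonequant.data") / "reference_cohort.csv"
    ) as p:
        return load_cohort_table(p)


def run_cohort_stats(
    cohort_csv: str | Path,
    metrics: Sequence[str] = DEFAULT_METRICS,
    output_dir: str | Path = ".",
    alpha: float = 0.05,
    posthoc_method: str = "asymptotic",
    seed: int | None = None,
) -> dict:
    """Cohort CSV -> stage summaries + omnibus + post hoc report files.

    Writes ``report.csv``, ``report.md`` and ``long_format.csv`` (for
    external boxplotting) plus provenance; returns the report objects.
    """
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort_table(cohort_csv)
    report = stage_comparison_report(
        cohort, metrics=metrics, alpha=alpha, posthoc_method=posthoc_method, seed=seed
    )
    frame = report_to_frame(report)
    frame.to_csv(out_dir / "report.csv", index=False)
    (out_dir / "report.md").write_text(report_to_markdown(report, alpha=alpha))
    cohort_long_format(cohort, metrics).to_csv(
        out_dir / "long_format.csv", index=False
    )
    cfg = {
        "cohort_csv": str(cohort_csv),
        "metrics": list(metrics),
        "alpha": alpha,
        "posthoc_method": posthoc_method,
        "seed": seed,
    }
    _write_provenance(
        out_dir,
        {"command": "stats", "config": cfg, "config_hash": _config_hash(cfg)},
    )
    return {"report": report, "frame": frame, "cohort": cohort}
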