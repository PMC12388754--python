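"""Run configuration and the end-to-end analysis pipeline."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .exceptions import FoulfitError, ValidationError
from .flux import read_flux_csv
from .performance import stage_performance
from .report import fits_frame, write_report_json
from .selection import rank_mechanisms
from .stages import StageAssay

logger = logging.getLogger("foulfit")

__all__ = ["RunConfig", "run_pipeline", "read_assay_csv"]


class RunConfig(BaseModel):
    """Configuration for a full simulate→fit→select→performance run."""

    inputs: list[str] = Field(..., description="stage flux CSV paths")
    family: str = Field("both", pattern="^(dead_end|crossflow|both)$")
    jo_mode: str = Field("first", pattern="^(first|intercept)$")
    mechanisms: list[str] | None = None
    dominance_threshold: float = Field(0.05, ge=0)
    residual_fraction: float = Field(0.4, gt=0, lt=1)
    assay_csv: str | None = None
    area: float | None = Field(None, gt=0)
    output_dir: str = "foulfit-out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def read_assay_csv(path) -> list[tuple[str, StageAssay, StageAssay]]:
    """Stage assay CSV: columns label,role,volume,lac,pro (role: feed/retentate)."""
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"label", "role", "volume", "lac", "pro"}
    if not required <= set(df.columns):
        raise ValidationError(f"assay CSV needs columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        roles = {str(r).strip().lower(): row for r, row in zip(grp["role"], grp.itertuples())}
        if not {"feed", "retentate"} <= roles.keys():
            raise ValidationError(f"stage {label!r} needs one feed and one retentate row")
        feed = roles["feed"]
        ret = roles["retentate"]
        out.append((
            str(label),
            StageAssay(feed.volume, feed.lac, feed.pro, label=f"{label} feed"),
            StageAssay(ret.volume, ret.lac, ret.pro, label=f"{label} retentate"),
        ))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Fit every stage CSV with the configured families and mechanisms.

    Per stage, writes a JSON mechanism report and appends to a parameter
    table CSV; failures are logged and the run continues.  Returns the
    report bundle; raises only if every stage fails.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    families = ["dead_end", "crossflow"] if config.family == "both" else [config.family]

    if not config.inputs:
        raise ValidationError("no input stage CSVs given")

    bundle: dict = {"stages": {}, "failures": {}}
    reports = []
    for path in config.inputs:
        label = Path(path).stem
        try:
            series = read_flux_csv(path, area=config.area).with_label(label)
            stage_reports = {}
            stage_objs = []
            for family in families:
                rep = rank_mechanisms(
                    series, family=family,
                    threshold=config.dominance_threshold,
                )
                stage_reports[family] = rep.to_dict()
                stage_objs.append(rep)
            if not any(rep.ranking for rep in stage_objs):
                raise FoulfitError("every blocking-law fit was rejected")
            reports.extend(stage_objs)
            bundle["stages"][label] = stage_reports
            write_report_json(stage_reports, outdir / f"{label}.report.json")
        except FoulfitError as exc:
            logger.error("stage %s failed: %s", label, exc)
            bundle["failures"][label] = str(exc)

    if not bundle["stages"]:
        raise FoulfitError("all stages failed; nothing to report")

    fits_frame(reports).to_csv(outdir / "blocking_parameters.csv", index=False)

    if config.assay_csv:
        rows = [
            stage_performance(feed, ret, stage_label=label).as_row()
            for label, feed, ret in read_assay_csv(config.assay_csv)
        ]
        perf = pd.DataFrame(rows)
        perf.to_csv(outdir / "performance.csv", index=False)
        bundle["performance"] = perf.to_dict(orient="records")

    with open(outdir / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
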