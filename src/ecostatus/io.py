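"""Reading indicator tables/matrices, run configuration, and the JSON report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .aggregation import AggregationConfig, EarlyWarningConfig
from .bayes import GESAssessment
from .indicators import IndicatorSeries, IndicatorSet, derive_target
from .ordination import IndicatorMatrix

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["id", "label", "group", "year", "mean", "sd", "unit", "direction", "target"]
_SEPARATORS = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def read_indicator_table(
    path,
    strict: bool = True,
    target_method: str = "percentile",
    percentile_q: float = 0.5,
) -> IndicatorSet:
    """Read a long-format indicator table into a validated IndicatorSet.

    One row per (indicator, year) with mandatory header
    ``id,label,group,year,mean,sd,unit,direction,target``. A blank target is
    derived from the series itself (default: median of the observed means).
    With ``strict=False`` malformed rows are skipped with a logged warning
    naming the line; duplicated (id, year) pairs are always an error.
    """
    path = Path(path)
    sep = _SEPARATORS.get(path.suffix.lower(), ",")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing}")

    rows = []
    for i, row in df.iterrows():
        line_no = i + 2  # 1-based, after header
        try:
            rows.append({
                "id": row["id"].strip(),
                "label": row["label"],
                "group": row["group"],
                "year": int(row["year"]),
                "mean": float(row["mean"]),
                "sd": float(row["sd"]),
                "unit": row["unit"],
                "direction": row["direction"].strip(),
                "target": float(row["target"]) if row["target"].strip() else None,
            })
        except (ValueError, TypeError) as exc:
            msg = f"{path.name} line {line_no}: {exc} (row: {row.to_dict()})"
            if strict:
                raise ValueError(msg) from exc
            logger.warning("skipping malformed row — %s", msg)

    parsed = pd.DataFrame(rows)
    if parsed.empty:
        raise ValueError(f"{path.name}: no valid indicator rows")
    dupes = parsed.duplicated(subset=["id", "year"])
    if dupes.any():
        pairs = parsed.loc[dupes, ["id", "year"]].to_records(index=False).tolist()
        raise ValueError(f"{path.name}: duplicated (id, year) rows: {pairs}")

    series = []
    for ind_id, grp in parsed.groupby("id", sort=False):
        grp = grp.sort_values("year")
        targets = {t for t in grp["target"] if t is not None}
        if len(targets) > 1:
            raise ValueError(f"indicator {ind_id!r}: conflicting target values {targets}")
        s = IndicatorSeries(
            id=ind_id,
            times=tuple(grp["year"]),
            means=tuple(grp["mean"]),
            sds=tuple(grp["sd"]),
            direction=grp["direction"].iloc[0],
            target=targets.pop() if targets else None,
            label=grp["label"].iloc[0],
            group=grp["group"].iloc[0],
            unit=grp["unit"].iloc[0],
        )
        if s.target is None:
            t = derive_target(s, target_method, percentile_q=percentile_q)
            logger.info("indicator %r: derived %s target %.6g", ind_id, target_method, t)
            s = s.with_target(t, basis="percentile")
        series.append(s)
    return IndicatorSet(tuple(series))


def write_indicator_table(indicator_set: IndicatorSet, path) -> None:
    rows = []
    for s in indicator_set:
        for year, mean, sd in zip(s.times, s.means, s.sds):
            rows.append({
                "id": s.id, "label": s.label, "group": s.group, "year": year,
                "mean": mean, "sd": sd, "unit": s.unit, "direction": s.direction,
                "target": s.target if s.target is not None else "",
            })
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, index=False)


def read_indicator_matrix(path) -> IndicatorMatrix:
    """Read a wide matrix CSV (first column year, one column per indicator)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{Path(path).name}: need a year column and >= 2 indicators")
    df = df.set_index(df.columns[0])
    return IndicatorMatrix.from_dataframe(df)


def write_indicator_matrix(m: IndicatorMatrix, path) -> None:
    df = m.to_dataframe()
    df.index.name = "year"
    df.to_csv(path)


class RunConfig(BaseModel):
    """Assessment run settings; round-trips losslessly through YAML."""

    indicator_table: str
    matrix: str | None = None
    method: str = "bayes_additive"
    prior0: float = Field(default=0.5, gt=0, lt=1)
    clip_eps: float = 1e-9
    precaution: float = Field(default=0.0, ge=0)
    distribution: str = "normal"
    discount: float = Field(default=1.0, ge=0, le=1)
    warning_threshold: float = 0.25
    warning_k: int = 3
    target_method: str = "percentile"
    percentile_q: float = 0.5
    select: bool = False
    k_max: int = 2
    goal_share: float | None = None
    independence_threshold: float = 0.5
    years: str = "common"
    out_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def aggregation_config(self) -> AggregationConfig:
        return AggregationConfig(
            method=self.method,
            prior0=self.prior0,
            clip_eps=self.clip_eps,
            precaution=self.precaution,
            distribution=self.distribution,
            discount=self.discount,
            early_warning=EarlyWarningConfig(self.warning_threshold, self.warning_k),
        )


class WarningRecord(BaseModel):
    indicator_id: str
    start: int
    end: int
    side: str
    mean_p: float


class AssessmentReport(BaseModel):
    """Serializable assessment result (the published report schema)."""

    times: list[int]
    indicator_ids: list[str]
    posterior: list[float]
    prior_chain: list[float]
    likelihoods: list[list[float]]
    warnings: list[WarningRecord] = []
    explained_variance: float | None = None
    selected_indicators: list[str] | None = None
    share_trajectory: list[float] | None = None
    config: dict = {}
    seed: int | None = None

    @classmethod
    def from_assessment(cls, a: GESAssessment, **extra) -> "AssessmentReport":
        cfg = a.config
        return cls(
            times=list(a.times),
            indicator_ids=list(a.indicator_ids),
            posterior=list(a.posterior),
            prior_chain=list(a.prior_chain),
            likelihoods=np.asarray(a.likelihoods).tolist(),
            warnings=[
                WarningRecord(indicator_id=w.indicator_id, start=w.start,
                              end=w.end, side=w.side, mean_p=w.mean_p)
                for w in a.warnings
            ],
            explained_variance=a.explained_variance,
            config={
                "method": cfg.method, "prior0": cfg.prior0,
                "clip_eps": cfg.clip_eps, "precaution": cfg.precaution,
                "distribution": cfg.distribution, "discount": cfg.discount,
                "warning_threshold": cfg.early_warning.threshold,
                "warning_k": cfg.early_warning.k,
            },
            **extra,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def export_report_schema(path) -> None:
    """Write the JSON schema the assessment report validates against."""
    Path(path).write_text(json.dumps(AssessmentReport.model_json_schema(), indent=2) + "\n")


def summary_text(report: AssessmentReport) -> str:
    """Plain-text summary of an assessment report."""
    lines = [
        f"Assessment over {len(report.times)} year(s), "
        f"{len(report.indicator_ids)} indicator(s)",
        f"  initial prior P(GES) = {report.prior_chain[0]:.3f}",
    ]
    for t, post in zip(report.times, report.posterior):
        lines.append(f"  {t}: P(GES) = {100 * post:.1f}%")
    if report.explained_variance is not None:
        lines.append(
            f"  explained ecosystem variance = {100 * report.explained_variance:.0f}% "
            f"(unexplained complement {100 * (1 - report.explained_variance):.0f}%)"
        )
    if report.selected_indicators:
        lines.append(f"  selected indicators: {', '.join(report.selected_indicators)}")
    if report.warnings:
        for w in report.warnings:
            lines.append(
                f"  early warning: {w.indicator_id} scored {w.side} "
                f"({w.start}-{w.end}, mean p = {w.mean_p:.3f})"
            )
    else:
        lines.append("  no early warnings")
    return "\n".join(lines) + "\n"
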