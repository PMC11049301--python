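"""End-to-end qualification pipeline.

Stage order mirrors a qualification campaign: homogeneity, then
stability, then commutability of the surviving materials, then
proficiency-testing performance.  A material that fails homogeneity or
stability is marked *not qualified* and excluded from the downstream
commutability and performance sections.  Stages whose inputs are not
configured are marked skipped and the run continues.

Outputs are deterministic: re-running with identical inputs and config
reproduces byte-identical CSV/JSON files, and the bundle records a
config hash so every number is traceable to an input file plus a
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .commutability import DemingRegression, characterize_materials
from .datatypes import MaterialPoint, TargetSpec
from .homogeneity import HomogeneityAnalysis
from .io import (read_material_replicates, read_paired_samples,
                 read_pt_results, read_replicate_tables,
                 read_stability_series, write_csv, write_json_report)
from .performance import PerformanceEvaluation
from .stability import StabilityTrend

logger = logging.getLogger("commutakit")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]


class RunConfig(BaseModel):
    """Pipeline configuration (YAML/JSON friendly)."""

    alpha: float = Field(0.05, gt=0, lt=1)
    band_level: float = Field(0.95, gt=0, lt=1)
    compatibility_threshold: float = Field(5.0, gt=0)
    satisfaction_abs: float = Field(15.0, gt=0)
    satisfaction_rel: float = Field(0.15, gt=0)
    percent_denominator: str = "reference"
    deming_lambda: float = Field(1.0, gt=0)
    stability_limits_pct: float | None = Field(10.0, gt=0)
    checkpoint_days: list[float] | None = None
    seed: int = 0

    homogeneity_csv: str | None = None
    stability_csv: str | None = None
    pairs_csv: str | None = None
    materials_csv: str | None = None
    pt_csv: str | None = None
    reference_method: str = "reference"
    reference_targets: dict[str, float] = Field(default_factory=dict)
    out_dir: str = "commutakit_out"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ReportBundle:
    """Collected stage outputs plus run metadata."""

    config_hash: str
    version: str
    homogeneity: list[dict] = field(default_factory=list)
    stability: list[dict] = field(default_factory=list)
    commutability: dict[str, Any] = field(default_factory=dict)
    performance: list[dict] = field(default_factory=list)
    qualified_materials: list[str] = field(default_factory=list)
    disqualified_materials: list[str] = field(default_factory=list)
    skipped_sections: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metadata": {"config_hash": self.config_hash,
                         "package_version": self.version},
            "homogeneity": self.homogeneity,
            "stability": self.stability,
            "commutability": self.commutability,
            "performance": self.performance,
            "qualified_materials": self.qualified_materials,
            "disqualified_materials": self.disqualified_materials,
            "skipped_sections": self.skipped_sections,
        }


def _material_points_from_replicates(
    df: pd.DataFrame, reference_method: str,
) -> dict[str, list[MaterialPoint]]:
    """Per-method material points from a tidy replicate frame."""
    stats = (df.groupby(["method", "material_id"])["value"]
               .agg(["mean", "std", "count"]))
    out: dict[str, list[MaterialPoint]] = {}
    methods = [m for m in df["method"].unique() if m != reference_method]
    for meth in methods:
        pts = []
        for mat in sorted(df["material_id"].unique()):
            try:
                ref_row = stats.loc[(reference_method, mat)]
                row = stats.loc[(meth, mat)]
            except KeyError:
                continue
            pts.append(MaterialPoint(
                material_id=str(mat),
                x_mean=float(ref_row["mean"]), x_sd=float(ref_row["std"]),
                y_mean=float(row["mean"]), y_sd=float(row["std"]),
                x_n=int(ref_row["count"]), y_n=int(row["count"])))
        out[meth] = pts
    return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(config_hash=config.config_hash(),
                          version=__version__)
    disqualified: set[str] = set()
    seen: set[str] = set()

    if config.homogeneity_csv:
        for table in read_replicate_tables(config.homogeneity_csv):
            seen.add(table.material_id)
            report = HomogeneityAnalysis(table, config.alpha).fit()
            bundle.homogeneity.append(report.to_dict())
            if not report.adequate:
                disqualified.add(table.material_id)
                logger.warning("material %s failed homogeneity",
                               table.material_id)
        write_csv(pd.DataFrame(
            [HomogeneityAnalysis.from_dataframe(
                pd.read_csv(config.homogeneity_csv), m).fit().summary_row()
             for m in sorted(seen)]),
            out / "homogeneity_summary.csv")
    else:
        bundle.skipped_sections.append("homogeneity")

    if config.stability_csv:
        rows = []
        for series in read_stability_series(config.stability_csv):
            seen.add(series.material_id)
            model = StabilityTrend(
                series, checkpoint_days=config.checkpoint_days,
                alpha=config.alpha, level=config.band_level,
                limits_pct=config.stability_limits_pct)
            res = model.fit()
            bundle.stability.append(res.to_dict())
            rows.extend({"material_id": series.material_id} | r
                        for r in (c.summary_row() for c in res.checkpoints))
            if not res.all_acceptable:
                disqualified.add(series.material_id)
                logger.warning("material %s failed stability",
                               series.material_id)
        write_csv(pd.DataFrame(rows), out / "stability_summary.csv")
    else:
        bundle.skipped_sections.append("stability")

    qualified = sorted(seen - disqualified)
    bundle.qualified_materials = qualified
    bundle.disqualified_materials = sorted(disqualified)

    if config.pairs_csv and config.materials_csv:
        pairs = read_paired_samples(config.pairs_csv)
        reps = read_material_replicates(config.materials_csv)
        # materials never seen by qualification are allowed through but
        # flagged; materials that failed qualification are dropped
        reps = reps[~reps["material_id"].isin(disqualified)]
        if reps.empty:
            bundle.skipped_sections.append("commutability")
        else:
            points = _material_points_from_replicates(
                reps, config.reference_method)
            _, tukey = characterize_materials(
                reps.rename(columns={"value": "value"}),
                config.reference_method)
            section: dict[str, Any] = {}
            rows = []
            for meth, pts in points.items():
                model = DemingRegression(
                    pairs, lambda_=config.deming_lambda,
                    level=config.band_level,
                    denominator=config.percent_denominator)
                res = model.fit(pts)
                section[meth] = res.to_dict()
                for v in res.verdicts:
                    rows.append({"method": meth} | v.summary_row())
            bundle.commutability = section
            write_csv(pd.DataFrame(rows),
                      out / "commutability_summary.csv")
    else:
        bundle.skipped_sections.append("commutability")

    if config.pt_csv:
        rows = []
        for rset in read_pt_results(config.pt_csv):
            if rset.material_id in disqualified:
                logger.warning("skipping PT scoring for disqualified "
                               "material %s", rset.material_id)
                continue
            ref_val = config.reference_targets.get(rset.material_id)
            reference = (TargetSpec("reference", ref_val)
                         if ref_val else None)
            res = PerformanceEvaluation(rset, reference=reference).fit()
            bundle.performance.append(res.to_dict())
            rows.append(res.summary())
        if rows:
            write_csv(pd.concat(rows, ignore_index=True),
                      out / "performance_summary.csv")
    else:
        bundle.skipped_sections.append("performance")

    write_json_report(bundle.to_dict(), out / "report.json")
    return bundle
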