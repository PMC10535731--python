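"""Pipeline orchestration and report rendering.

``run_pipeline`` executes whichever stages the supplied inputs allow
(viability -> clonogenic -> growth -> cohort) and assembles a
``ReportBundle`` of summary tables plus provenance (config hash, input
digests, package version).  Every number in a rendered table comes from
the owning module's operation; this layer does no arithmetic of its own.
Re-running on unchanged inputs and config yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .assay_io import RunConfig, read_table
from .clonogenic import classify_bliss, plating_efficiency, survival_points
from .cohort import (
    DEFAULT_REFERENCE_RANGES,
    annotate_comparisons,
    flag_reference_ranges,
    relative_spleen_index,
    spleen_index,
    summarize_groups,
)
from .growth import (
    growth_summaries,
    inhibition_summaries,
    trajectories_from_measurements,
)
from .viability import build_curve, estimate_ic50, NotEstimableError

logger = logging.getLogger(__name__)

__all__ = ["ReportBundle", "run_pipeline", "write_bundle"]


@dataclass
class ReportBundle:
    """All summary tables one run produces, plus provenance."""

    synergy_table: pd.DataFrame | None = None
    viability_table: pd.DataFrame | None = None
    ic50_um: float | None = None
    growth_table: pd.DataFrame | None = None
    inhibition_table: pd.DataFrame | None = None
    cohort_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _viability_stage(path: Path, config: RunConfig, bundle: ReportBundle) -> None:
    wells = read_table(path, "viability")
    curve = build_curve(wells, config.viability_coefficients)
    bundle.viability_table = pd.DataFrame(
        {
            "dose_um": curve.doses,
            "mean_viability_percent": curve.mean_viability,
            "se_viability_percent": curve.se_viability,
            "n": curve.n,
        }
    )
    try:
        bundle.ic50_um = estimate_ic50(curve, "log_interp")
        logger.info("IC50 (log interpolation): %.4g µM", bundle.ic50_um)
    except NotEstimableError as exc:
        logger.warning("IC50 not estimable: %s", exc)


def _clonogenic_stage(path: Path, config: RunConfig, bundle: ReportBundle) -> None:
    records = read_table(path, "clonogenic")
    pe = plating_efficiency(records)
    logger.info("plating efficiency %.4f", pe)
    points = survival_points(records, pe)
    by_cond = {(p.radiation_dose, p.condition): p for p in points}
    drug_only = [p for p in points if p.condition == "drug_only"]
    if not drug_only:
        raise ValueError("no drug-only (0 Gy) condition for Bliss scoring")
    sf_c = drug_only[0].sf
    rows = []
    for p in sorted(points, key=lambda p: p.radiation_dose):
        if p.condition != "radiation_only" or p.radiation_dose == 0:
            continue
        combo = by_cond.get((p.radiation_dose, "combination"))
        if combo is None or combo.sf <= 0 or p.sf <= 0:
            continue
        row = classify_bliss(
            p.sf, sf_c, combo.sf, radiation_dose=p.radiation_dose
        )
        rows.append(
            {
                "radiation_gy": row.radiation_dose,
                "sf_r": row.sf_r,
                "sf_c": row.sf_c,
                "bliss_product": row.bliss_product,
                "sf_observed": row.sf_observed,
                "verdict": row.verdict,
            }
        )
        logger.info(
            "dose %g Gy: SF_R=%.3g SF_C=%.3g product=%.3g observed=%.3g -> %s",
            row.radiation_dose, row.sf_r, row.sf_c, row.bliss_product,
            row.sf_observed, row.verdict,
        )
    bundle.synergy_table = pd.DataFrame(rows)


def _growth_stage(path: Path, config: RunConfig, bundle: ReportBundle) -> None:
    measurements = read_table(path, "caliper")
    trajectories = trajectories_from_measurements(
        measurements, config.volume_constant
    )
    growth = growth_summaries(trajectories, config)
    bundle.growth_table = pd.DataFrame(
        [
            {
                "group": s.group,
                "n": s.n,
                "mean_growth_time_days": s.mean_growth_time,
                "delay_days": s.delay_time,
                "time_ratio_rate": s.time_ratio_rate,
                "enhancement_vs_drug": s.enhancement_ratios.get("drug"),
                "enhancement_vs_radiation": s.enhancement_ratios.get("radiation"),
                "n_censored": s.n_censored,
            }
            for s in growth.values()
        ]
    )
    inhibition = inhibition_summaries(trajectories, config)
    bundle.inhibition_table = pd.DataFrame(
        [
            {
                "group": s.group,
                "n": s.n,
                "mean_volume_mm3": s.mean_volume_mm3,
                "inhibition_rate_percent": s.inhibition_rate,
                "expected_rate_percent": s.expected_rate,
                "combination_index": s.combination_index,
            }
            for s in inhibition.values()
        ]
    )


def _cohort_stage(path: Path, config: RunConfig, bundle: ReportBundle) -> None:
    animals = read_table(path, "animal")
    by_group: dict[str, list[float]] = {}
    for a in animals:
        by_group.setdefault(a.group, []).append(spleen_index(a))
    rows = []
    for s in summarize_groups(by_group, "spleen_index"):
        rows.append(
            {"group": s.group, "analyte": s.analyte, "mean": s.mean,
             "se": s.se, "n": s.n}
        )
    try:
        rsi = relative_spleen_index(animals)
        for g, v in rsi.items():
            rows.append(
                {"group": g, "analyte": "relative_spleen_index",
                 "mean": v, "se": None, "n": len(by_group.get(g, []))}
            )
    except ValueError as exc:
        logger.warning("relative spleen index skipped: %s", exc)
    annotations = annotate_comparisons(
        by_group, references=("control",),
        thresholds=config.significance_thresholds,
    )
    for ann in annotations:
        rows.append(
            {"group": ann.group, "analyte": "spleen_index_p_vs_control",
             "mean": ann.p_value, "se": None, "n": None}
        )
    # biochemistry: group means and reference-range flags
    analytes = sorted({k for a in animals for k in a.biochem})
    for analyte in analytes:
        grouped = {}
        for a in animals:
            if analyte in a.biochem:
                grouped.setdefault(a.group, []).append(a.biochem[analyte])
        for s in summarize_groups(grouped, analyte):
            flags = flag_reference_ranges(
                {analyte: s.mean}, DEFAULT_REFERENCE_RANGES
            )
            rows.append(
                {"group": s.group, "analyte": analyte, "mean": s.mean,
                 "se": s.se, "n": s.n,
                 "range_flag": flags.get(analyte)}
            )
    bundle.cohort_table = pd.DataFrame(rows)


_STAGES = {
    "viability": _viability_stage,
    "clonogenic": _clonogenic_stage,
    "caliper": _growth_stage,
    "animal": _cohort_stage,
}


def run_pipeline(
    config: RunConfig, inputs: Mapping[str, str | Path]
) -> ReportBundle:
    """Run every stage for which an input table was supplied.

    ``inputs`` maps schema names (``viability``, ``clonogenic``,
    ``caliper``, ``animal``) to CSV paths.  Missing inputs skip their stage
    with a logged notice; a failing stage is recorded in
    ``bundle.errors`` and does not abort the others.
    """
    known = set(_STAGES)
    unknown = set(inputs) - known
    if unknown:
        raise ValueError(f"unrecognized inputs {sorted(unknown)}")
    if not inputs:
        raise ValueError("no inputs supplied")

    bundle = ReportBundle()
    bundle.provenance = {
        "version": __version__,
        "config": config.model_dump(),
        "config_sha256": _config_hash(config),
        "inputs": {
            schema: {"path": str(p), "sha256": _digest(Path(p))}
            for schema, p in inputs.items()
        },
        "seed": config.seed,
    }
    for schema, stage in _STAGES.items():
        if schema not in inputs:
            logger.info("no %s input; stage skipped", schema)
            continue
        try:
            stage(Path(inputs[schema]), config, bundle)
        except Exception as exc:  # noqa: BLE001 - partial bundles are a contract
            logger.error("stage %s failed: %s", schema, exc)
            bundle.errors[schema] = str(exc)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write every table in the bundle plus a text summary; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "viability_curve.csv": bundle.viability_table,
        "synergy_table.csv": bundle.synergy_table,
        "growth_table.csv": bundle.growth_table,
        "inhibition_table.csv": bundle.inhibition_table,
        "cohort_table.csv": bundle.cohort_table,
    }
    for name, df in tables.items():
        if df is not None and not df.empty:
            path = out_dir / name
            df.to_csv(path, index=False)
            written.append(path)

    lines = ["radsyn report", "============="]
    if bundle.ic50_um is not None:
        lines.append(f"IC50 (log interpolation): {bundle.ic50_um:.4g} uM")
    for name, df in tables.items():
        if df is not None and not df.empty:
            lines.append("")
            lines.append(name)
            lines.append(df.to_string(index=False))
    if bundle.errors:
        lines.append("")
        lines.append("stage errors:")
        for schema, msg in sorted(bundle.errors.items()):
            lines.append(f"  {schema}: {msg}")
    lines.append("")
    lines.append("provenance: " + json.dumps(bundle.provenance, sort_keys=True, default=str))
    summary = out_dir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
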