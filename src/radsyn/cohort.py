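"""Immune and toxicity cohort summaries.

Spleen indices (spleen weight / body weight), relative spleen indices
normalized to the untreated normal group, per-group mean ± standard error
summaries of lymphocyte subsets and cytokines, tiered significance
annotations from two-sample t tests, and biochemistry reference-range
flags.

Annotation families follow the usual figure convention of this literature:
``*`` marks comparisons against the control group, ``#`` against the
radiation-alone group and ``$`` against the drug-alone group, with one,
two or three glyphs for p < 0.05, < 0.01 and < 0.001 respectively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .assay_io import AnimalRecord, canonical_group

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "ComparisonAnnotation",
    "ReferenceRange",
    "DEFAULT_REFERENCE_RANGES",
    "REFERENCE_GLYPHS",
    "spleen_index",
    "relative_spleen_index",
    "summarize_groups",
    "annotate_comparisons",
    "flag_reference_ranges",
]

#: Annotation glyph per reference family.
REFERENCE_GLYPHS: Mapping[str, str] = {
    "control": "*",
    "radiation": "#",
    "drug": "$",
    "normal": "*",
}


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± standard error of one analyte in one group."""

    group: str
    analyte: str
    mean: float
    se: float | None
    n: int


@dataclass(frozen=True)
class ComparisonAnnotation:
    """Significance tier of one group against one reference group."""

    group: str
    reference: str
    p_value: float
    symbol: str


@dataclass(frozen=True)
class ReferenceRange:
    """Normal range of a serum analyte."""

    analyte: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("reference range requires low < high")


#: Vendor (Charles River) reference ranges for BALB/c serum biochemistry.
DEFAULT_REFERENCE_RANGES: tuple[ReferenceRange, ...] = (
    ReferenceRange("alp", 62.0, 209.0, "U/L"),
    ReferenceRange("alb", 2.5, 4.8, "g/dL"),
    ReferenceRange("alt", 28.0, 132.0, "U/L"),
    ReferenceRange("ast", 59.0, 247.0, "U/L"),
    ReferenceRange("bun", 18.0, 29.0, "mg/dL"),
    ReferenceRange("cre", 0.2, 0.8, "mg/dL"),
)


def spleen_index(animal: AnimalRecord) -> float:
    """Spleen weight divided by body weight (dimensionless)."""
    if animal.body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    index = animal.spleen_weight_g / animal.body_weight_g
    if index >= 1:
        logger.warning(
            "animal %s: spleen index %.3f >= 1 (degenerate weights)",
            animal.animal_id,
            index,
        )
    return index


def relative_spleen_index(
    animals: Iterable[AnimalRecord],
) -> dict[str, float]:
    """Per-group mean spleen index normalized so the normal group is 1.

    The normal (tumor-free, untreated) group anchors the scale and its RSI
    is exactly 1 by construction.
    """
    by_group: dict[str, list[float]] = {}
    for a in animals:
        by_group.setdefault(a.group, []).append(spleen_index(a))
    if "normal" not in by_group:
        raise ValueError("normal group required to anchor the RSI")
    normal_mean = float(np.mean(by_group["normal"]))
    rsi = {
        g: float(np.mean(v)) / normal_mean for g, v in by_group.items()
    }
    rsi["normal"] = 1.0
    return rsi


def summarize_groups(
    values_by_group: Mapping[str, Sequence[float]],
    analyte: str,
) -> list[GroupSummary]:
    """Mean and standard error (sd/sqrt(n), sd with n-1 dof) per group.

    A single-animal group has an undefined standard error, reported as
    missing (None).
    """
    summaries = []
    for group, values in values_by_group.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {group!r} has no values")
        se = (
            float(arr.std(ddof=1) / math.sqrt(arr.size))
            if arr.size > 1
            else None
        )
        summaries.append(
            GroupSummary(
                group=canonical_group(group),
                analyte=analyte,
                mean=float(arr.mean()),
                se=se,
                n=int(arr.size),
            )
        )
    return summaries


def _tier_symbol(p: float, glyph: str, thresholds: Sequence[float]) -> str:
    return glyph * sum(p < t for t in thresholds)


def annotate_comparisons(
    values_by_group: Mapping[str, Sequence[float]],
    references: Sequence[str] = ("control",),
    thresholds: Sequence[float] = (0.05, 0.01, 0.001),
    welch: bool = False,
) -> list[ComparisonAnnotation]:
    """Tiered significance annotations of each group against references.

    Runs a two-sided two-sample Student t test (pooled variance by default;
    Welch optionally) of every non-reference group against each reference
    group present, and renders the p value as 0-3 repeats of the
    reference's glyph.  Pairs where either side has fewer than two animals
    are skipped with a warning.
    """
    data = {canonical_group(g): np.asarray(list(v), float)
            for g, v in values_by_group.items()}
    annotations: list[ComparisonAnnotation] = []
    for ref in references:
        ref = canonical_group(ref)
        if ref not in data:
            continue
        glyph = REFERENCE_GLYPHS.get(ref, "*")
        for group, values in data.items():
            if group == ref:
                continue
            if len(values) < 2 or len(data[ref]) < 2:
                logger.warning(
                    "skipping %s vs %s: fewer than 2 animals per side",
                    group,
                    ref,
                )
                continue
            result = stats.ttest_ind(
                values, data[ref], equal_var=not welch
            )
            p = float(result.pvalue)
            annotations.append(
                ComparisonAnnotation(
                    group=group,
                    reference=ref,
                    p_value=p,
                    symbol=_tier_symbol(p, glyph, thresholds),
                )
            )
    return annotations


def flag_reference_ranges(
    group_means: Mapping[str, float],
    ranges: Iterable[ReferenceRange] = DEFAULT_REFERENCE_RANGES,
) -> dict[str, Literal["within", "below", "above"]]:
    """Compare analyte means to reference ranges (inclusive bounds).

    Analytes without a known range are left unflagged with a warning.
    """
    by_analyte = {r.analyte.lower(): r for r in ranges}
    flags: dict[str, Literal["within", "below", "above"]] = {}
    for analyte, mean in group_means.items():
        rng = by_analyte.get(analyte.lower())
        if rng is None:
            logger.warning("no reference range for analyte %r", analyte)
            continue
        if mean < rng.low:
            flags[analyte] = "below"
        elif mean > rng.high:
            flags[analyte] = "above"
        else:
            flags[analyte] = "within"
    return flags
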