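"""In vivo efficacy analysis: caliper volumes, growth delay, Bliss index.

Two distinct group-level "inhibition" notions coexist in preclinical
radiosensitizer studies and are deliberately kept apart here:

* the **time-ratio rate** (treated mean growth time / control mean growth
  time), the basis of growth-delay and combination-enhancement-ratio
  summaries, and
* the **volume-based rate** ``(1 - treated mean volume / control mean
  volume) * 100`` at a fixed evaluation day, the basis of the Bliss
  expected rate and the combination index

    CI = (1 - observed/100) / (1 - expected/100),

  with CI < 1 synergism, CI = 1 additivity, CI > 1 antagonism.

``precision_mode="printed"`` reproduces the common publication practice of
computing ratios from already-rounded intermediates (two-decimal time
rates, whole-percent volume rates); ``"full"`` keeps full floating-point
precision throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .assay_io import CaliperMeasurement, RunConfig, canonical_group

logger = logging.getLogger(__name__)

__all__ = [
    "TumorTrajectory",
    "GrowthTimeResult",
    "GrowthSummary",
    "InhibitionSummary",
    "tumor_volume",
    "trajectories_from_measurements",
    "growth_time",
    "growth_summaries",
    "summarize_growth_times",
    "volume_inhibition_rate",
    "bliss_expected_rate",
    "combination_index",
    "classify_combination_index",
    "inhibition_summaries",
    "group_mean_volume",
    "EXACT_ELLIPSOID_CONSTANT",
]

PrecisionMode = Literal["printed", "full"]

#: 4*pi/24 — the exact ellipsoid constant; 0.523 is its conventional
#: three-digit truncation used in caliper formulas.
EXACT_ELLIPSOID_CONSTANT = 4.0 * math.pi / 24.0


def _round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class TumorTrajectory:
    """One animal's tumor volume time series (days ascending, mm³)."""

    animal_id: str
    group: str
    days: tuple[float, ...]
    volumes_mm3: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", canonical_group(self.group))
        d = np.asarray(self.days)
        if d.size != len(self.volumes_mm3):
            raise ValueError("days and volumes must align")
        if d.size and not np.all(np.diff(d) > 0):
            raise ValueError("days must strictly increase")
        if any(v < 0 for v in self.volumes_mm3):
            raise ValueError("volumes must be non-negative")


@dataclass(frozen=True)
class GrowthTimeResult:
    """Time (days) for a trajectory to reach a volume threshold.

    ``censored`` is True when the threshold is never reached within the
    observation window; ``days`` is then the last observed day (a lower
    bound, excluded from group means).
    """

    days: float
    censored: bool = False


@dataclass(frozen=True)
class GrowthSummary:
    """Group-level growth-time metrics (time-ratio family)."""

    group: str
    n: int
    mean_growth_time: float
    delay_time: float | None
    time_ratio_rate: float | None
    enhancement_ratios: Mapping[str, float] = field(default_factory=dict)
    n_censored: int = 0


@dataclass(frozen=True)
class InhibitionSummary:
    """Group-level volume-based inhibition at the evaluation day."""

    group: str
    n: int
    mean_volume_mm3: float
    inhibition_rate: float | None
    expected_rate: float | None = None
    combination_index: float | None = None


def tumor_volume(
    length_mm: float,
    width_mm: float,
    height_mm: float,
    constant: float = 0.523,
) -> float:
    """Ellipsoid tumor volume from a caliper triplet.

    volume = constant * L * W * H.  The default 0.523 is the conventional
    truncation of the exact (4/3)π(L/2)(W/2)(H/2) = (4π/24)·L·W·H;
    pass ``EXACT_ELLIPSOID_CONSTANT`` for the exact form.
    """
    if min(length_mm, width_mm, height_mm) < 0:
        raise ValueError("caliper dimensions must be non-negative")
    return constant * length_mm * width_mm * height_mm


def trajectories_from_measurements(
    measurements: Iterable[CaliperMeasurement],
    volume_constant: float = 0.523,
) -> list[TumorTrajectory]:
    """Assemble per-animal trajectories from caliper rows.

    Volumes are taken from ``volume_mm3`` when present, else computed from
    the dimension triplet.
    """
    by_animal: dict[str, list[CaliperMeasurement]] = {}
    for m in measurements:
        by_animal.setdefault(m.animal_id, []).append(m)
    trajectories = []
    for animal_id, rows in by_animal.items():
        rows.sort(key=lambda r: r.day)
        groups = {r.group for r in rows}
        if len(groups) != 1:
            raise ValueError(
                f"animal {animal_id!r} appears in multiple groups: {groups}"
            )
        volumes = []
        for r in rows:
            if r.volume_mm3 is not None:
                volumes.append(r.volume_mm3)
            else:
                volumes.append(
                    tumor_volume(
                        r.length_mm, r.width_mm, r.height_mm, volume_constant
                    )
                )
        trajectories.append(
            TumorTrajectory(
                animal_id=animal_id,
                group=groups.pop(),
                days=tuple(r.day for r in rows),
                volumes_mm3=tuple(volumes),
            )
        )
    return trajectories


def growth_time(
    traj: TumorTrajectory, threshold_mm3: float
) -> GrowthTimeResult:
    """Day the trajectory first reaches a volume threshold.

    Between measurement days the crossing is located by linear
    interpolation of ln(volume) against day (tumor growth is near-
    exponential at small volumes).  If the first observation is already at
    or above threshold its day is returned; if the threshold is never
    reached the result is censored.
    """
    if threshold_mm3 <= 0:
        raise ValueError("threshold must be positive")
    vols = traj.volumes_mm3
    days = traj.days
    if not vols:
        raise ValueError("empty trajectory")
    if vols[0] >= threshold_mm3:
        return GrowthTimeResult(days=days[0])
    for i in range(1, len(vols)):
        if vols[i] >= threshold_mm3:
            v0, v1 = vols[i - 1], vols[i]
            if v0 <= 0:
                # cannot log-interpolate from zero; attribute to the day of
                # first attainment
                return GrowthTimeResult(days=days[i])
            frac = (math.log(threshold_mm3) - math.log(v0)) / (
                math.log(v1) - math.log(v0)
            )
            return GrowthTimeResult(
                days=days[i - 1] + frac * (days[i] - days[i - 1])
            )
    return GrowthTimeResult(days=days[-1], censored=True)


def summarize_growth_times(
    times_by_group: Mapping[str, Sequence[float]],
    precision_mode: PrecisionMode = "full",
    censored_by_group: Mapping[str, int] | None = None,
) -> dict[str, GrowthSummary]:
    """Growth-delay summary from per-animal growth times.

    Per group: mean growth time; delay = group mean - control mean;
    time-ratio rate = group mean / control mean; for the combination group,
    one enhancement ratio per single-agent group (combination rate /
    single-agent rate).  In printed mode the rates are rounded to two
    decimals before entering the enhancement ratios, and all outputs are
    rounded to two decimals.
    """
    groups = {canonical_group(g): list(v) for g, v in times_by_group.items()}
    if "control" not in groups or not groups["control"]:
        raise ValueError("control group with >= 1 uncensored animal required")
    for g, v in groups.items():
        if not v:
            raise ValueError(f"group {g!r} has no uncensored growth times")
    censored_by_group = censored_by_group or {}

    printed = precision_mode == "printed"

    control_mean = float(np.mean(groups["control"]))
    rates: dict[str, float] = {}
    means: dict[str, float] = {}
    for g, v in groups.items():
        means[g] = float(np.mean(v))
        rate = means[g] / control_mean
        rates[g] = _round_half_away(rate, 2) if printed else rate

    summaries: dict[str, GrowthSummary] = {}
    for g, v in groups.items():
        enhancement: dict[str, float] = {}
        if g == "combination":
            for comparator in ("drug", "radiation"):
                if comparator in rates:
                    er = rates[g] / rates[comparator]
                    enhancement[comparator] = (
                        _round_half_away(er, 2) if printed else er
                    )
        delay = None if g == "control" else means[g] - control_mean
        if printed and delay is not None:
            delay = _round_half_away(delay, 2)
        summaries[g] = GrowthSummary(
            group=g,
            n=len(v),
            mean_growth_time=means[g],
            delay_time=delay,
            time_ratio_rate=rates[g],
            enhancement_ratios=enhancement,
            n_censored=int(censored_by_group.get(g, 0)),
        )
    return summaries


def growth_summaries(
    trajectories: Iterable[TumorTrajectory],
    config: RunConfig | None = None,
) -> dict[str, GrowthSummary]:
    """Per-group growth-delay summary from trajectories.

    Censored animals (never reaching the threshold) are excluded from the
    group mean with a logged warning.
    """
    config = config or RunConfig()
    times: dict[str, list[float]] = {}
    censored: dict[str, int] = {}
    for traj in trajectories:
        result = growth_time(traj, config.growth_threshold_mm3)
        if result.censored:
            censored[traj.group] = censored.get(traj.group, 0) + 1
            logger.warning(
                "animal %s (%s) never reached %g mm³; censored at day %g "
                "and excluded from the group mean",
                traj.animal_id,
                traj.group,
                config.growth_threshold_mm3,
                result.days,
            )
        else:
            times.setdefault(traj.group, []).append(result.days)
    return summarize_growth_times(
        times, precision_mode=config.precision_mode, censored_by_group=censored
    )


def volume_inhibition_rate(
    group_mean_volume: float,
    control_mean_volume: float,
    precision_mode: PrecisionMode = "full",
) -> float:
    """Volume-based inhibition rate (%) at a fixed evaluation day.

    rate = (1 - treated/control) * 100.  A treated mean above control gives
    a negative rate (growth promotion), flagged in the log.  Printed mode
    rounds to the whole percent (half away from zero).
    """
    if control_mean_volume <= 0:
        raise ValueError("control mean volume must be positive")
    rate = (1.0 - group_mean_volume / control_mean_volume) * 100.0
    if rate < 0:
        logger.warning(
            "treated mean volume exceeds control (rate %.1f%%): growth "
            "promotion rather than inhibition",
            rate,
        )
    return _round_half_away(rate, 0) if precision_mode == "printed" else rate


def bliss_expected_rate(
    rate_a: float,
    rate_b: float,
    precision_mode: PrecisionMode = "full",
) -> float:
    """Bliss-independence expected inhibition (%) of a combination.

    With single-agent fractions r_a, r_b the expectation is
    (r_a + r_b - r_a*r_b) * 100 = (1 - (1-r_a)(1-r_b)) * 100; symmetric in
    its arguments.  Printed mode rounds the input rates to whole percent
    before combining and the output to the whole percent.
    """
    for name, r in (("rate_a", rate_a), ("rate_b", rate_b)):
        if not 0 <= r <= 100:
            raise ValueError(f"{name} must lie in [0, 100], got {r}")
    if precision_mode == "printed":
        rate_a = _round_half_away(rate_a, 0)
        rate_b = _round_half_away(rate_b, 0)
    ra, rb = rate_a / 100.0, rate_b / 100.0
    expected = (ra + rb - ra * rb) * 100.0
    return (
        _round_half_away(expected, 0)
        if precision_mode == "printed"
        else expected
    )


def combination_index(
    observed_rate: float,
    expected_rate: float,
    precision_mode: PrecisionMode = "full",
) -> float:
    """Combination index CI = (1 - observed/100) / (1 - expected/100).

    CI < 1 indicates synergism, CI = 1 additivity, CI > 1 antagonism.
    Printed mode rounds both rates to the whole percent first and the index
    to two decimals.
    """
    if precision_mode == "printed":
        observed_rate = _round_half_away(observed_rate, 0)
        expected_rate = _round_half_away(expected_rate, 0)
    if expected_rate >= 100:
        raise ValueError("combination index undefined at expected rate 100%")
    ci = (1.0 - observed_rate / 100.0) / (1.0 - expected_rate / 100.0)
    return _round_half_away(ci, 2) if precision_mode == "printed" else ci


def classify_combination_index(ci: float) -> str:
    """Verbal verdict for a combination index."""
    if ci <= 0:
        raise ValueError("combination index must be positive")
    if ci < 1:
        return "synergism"
    if ci > 1:
        return "antagonism"
    return "additivity"


def group_mean_volume(
    trajectories: Iterable[TumorTrajectory], group: str, day: float
) -> tuple[float, int]:
    """Mean tumor volume (mm³) of a group at a given day.

    The day must be inside each animal's observation window; volumes between
    measurement days are log-linearly interpolated (consistent with
    ``growth_time``).  Returns (mean, n animals).
    """
    group = canonical_group(group)
    vols = []
    for traj in trajectories:
        if traj.group != group:
            continue
        days = np.asarray(traj.days)
        if day < days[0] or day > days[-1]:
            raise ValueError(
                f"day {day} outside observation window of {traj.animal_id}"
            )
        idx = int(np.searchsorted(days, day))
        if idx < len(days) and days[idx] == day:
            vols.append(traj.volumes_mm3[idx])
        else:
            v0, v1 = traj.volumes_mm3[idx - 1], traj.volumes_mm3[idx]
            d0, d1 = days[idx - 1], days[idx]
            if v0 > 0 and v1 > 0:
                frac = (day - d0) / (d1 - d0)
                vols.append(
                    math.exp(
                        (1 - frac) * math.log(v0) + frac * math.log(v1)
                    )
                )
            else:
                vols.append(v0 + (v1 - v0) * (day - d0) / (d1 - d0))
    if not vols:
        raise ValueError(f"no animals in group {group!r}")
    return float(np.mean(vols)), len(vols)


def inhibition_summaries(
    trajectories: Iterable[TumorTrajectory],
    config: RunConfig | None = None,
) -> dict[str, InhibitionSummary]:
    """Volume-based inhibition, Bliss expected rate and CI per group.

    Rates are computed at ``config.evaluation_day`` against the control
    mean; the expected rate and combination index are attached to the
    combination group when both single-agent rates exist.
    """
    config = config or RunConfig()
    trajectories = list(trajectories)
    mode = config.precision_mode
    day = config.evaluation_day

    present = {t.group for t in trajectories}
    if "control" not in present:
        raise ValueError("control group required for inhibition rates")
    control_mean, n_control = group_mean_volume(trajectories, "control", day)

    summaries: dict[str, InhibitionSummary] = {}
    rates: dict[str, float] = {}
    for g in ("control", "radiation", "drug", "combination"):
        if g not in present:
            continue
        mean_vol, n = group_mean_volume(trajectories, g, day)
        rate = (
            None
            if g == "control"
            else volume_inhibition_rate(mean_vol, control_mean, mode)
        )
        if rate is not None:
            rates[g] = rate
        summaries[g] = InhibitionSummary(
            group=g,
            n=n,
            mean_volume_mm3=mean_vol,
            inhibition_rate=rate,
        )
    if "combination" in summaries and {"drug", "radiation"} <= rates.keys():
        expected = bliss_expected_rate(rates["drug"], rates["radiation"], mode)
        ci = combination_index(rates["combination"], expected, mode)
        base = summaries["combination"]
        summaries["combination"] = InhibitionSummary(
            group=base.group,
            n=base.n,
            mean_volume_mm3=base.mean_volume_mm3,
            inhibition_rate=base.inhibition_rate,
            expected_rate=expected,
            combination_index=ci,
        )
    return summaries
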