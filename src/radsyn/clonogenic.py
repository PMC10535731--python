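"""Clonogenic survival analysis and Bliss multiplicativity scoring.

The clonogenic assay measures reproductive cell survival: cells are plated
at known number, treated, and colonies (>= 50 cells) counted two weeks
later.  With plating efficiency PE (colonies per cell plated, untreated),

    SF = colonies / (cells plated * PE).

Synergy between a drug and radiation is judged per radiation dose by Bliss
independence on surviving fractions: independent action predicts the
combination surviving fraction SF_R+C equals the product SF_R * SF_C.  An
observed SF_R+C below the product is synergism, above is antagonism.

The module also provides a linear-quadratic fit, ln SF = -alpha*D -
beta*D^2, used for simulation support and survival-curve summaries, and the
exponential-phase doubling time T_d = (t - t0) * ln 2 / (ln N - ln N0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import nnls

from .assay_io import ClonogenicRecord

__all__ = [
    "SurvivalPoint",
    "SynergyRow",
    "CellCountSeries",
    "LQParameters",
    "plating_efficiency",
    "surviving_fraction",
    "survival_points",
    "classify_bliss",
    "infer_drug_sf",
    "fit_lq",
    "lq_survival",
    "doubling_time",
]

Condition = Literal["untreated", "radiation_only", "drug_only", "combination"]
Verdict = Literal["synergism", "additivity", "antagonism"]


@dataclass(frozen=True)
class SurvivalPoint:
    """Mean surviving fraction at one (radiation dose, condition).

    ``below_detection`` flags sf == 0 (no colonies); such points are kept in
    tables but excluded from log-domain fitting.
    """

    radiation_dose: float
    sf: float
    se_sf: float
    condition: Condition
    n_replicates: int = 1
    below_detection: bool = False
    #: pooled colony count behind this point (0 when unknown); used as an
    #: inverse log-variance weight in LQ fitting
    total_colonies: int = 0

    def __post_init__(self) -> None:
        if self.sf < 0 or self.se_sf < 0:
            raise ValueError("sf and se_sf must be non-negative")


@dataclass(frozen=True)
class SynergyRow:
    """Per-dose Bliss classification: product vs observed combination SF."""

    radiation_dose: float
    sf_r: float
    sf_c: float
    bliss_product: float
    sf_observed: float
    verdict: Verdict


@dataclass(frozen=True)
class CellCountSeries:
    """Viable cell counts over hours post-seeding."""

    times: tuple[float, ...]
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t.size != len(self.counts):
            raise ValueError("times and counts must align")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("times must strictly increase")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic survival parameters (alpha in 1/Gy, beta in 1/Gy²)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


def plating_efficiency(records: Iterable[ClonogenicRecord]) -> float:
    """Plating efficiency from untreated (0 Gy, 0 µM) dishes.

    Counts are pooled across replicates (ratio of totals), the
    minimum-variance estimate for Poisson colony counts.
    """
    untreated = [
        r for r in records if r.radiation_gy == 0 and r.drug_um == 0
    ]
    if not untreated:
        raise ValueError("no untreated (0 Gy, 0 µM) record for PE")
    colonies = sum(r.colonies for r in untreated)
    plated = sum(r.cells_plated for r in untreated)
    if colonies == 0:
        raise ValueError(
            "zero colonies in all untreated dishes; PE of 0 makes SF "
            "undefined"
        )
    return colonies / plated


def surviving_fraction(record: ClonogenicRecord, pe: float) -> float:
    """SF of one dish: colonies / (cells plated * PE)."""
    if pe <= 0:
        raise ValueError(f"plating efficiency must be positive, got {pe}")
    return record.colonies / (record.cells_plated * pe)


def _condition_of(record: ClonogenicRecord) -> Condition:
    if record.radiation_gy == 0 and record.drug_um == 0:
        return "untreated"
    if record.drug_um == 0:
        return "radiation_only"
    if record.radiation_gy == 0:
        return "drug_only"
    return "combination"


def survival_points(
    records: Iterable[ClonogenicRecord], pe: float | None = None
) -> list[SurvivalPoint]:
    """Aggregate replicate dishes into per-condition survival points.

    Replicate SFs sharing a (radiation dose, drug dose) condition are
    averaged; ``se_sf`` is the standard error across replicates (0 for a
    single dish).
    """
    records = list(records)
    if pe is None:
        pe = plating_efficiency(records)
    by_cond: dict[tuple[float, Condition], list[ClonogenicRecord]] = {}
    for r in records:
        key = (r.radiation_gy, _condition_of(r))
        by_cond.setdefault(key, []).append(r)
    points = []
    for (dose, cond), recs in sorted(by_cond.items()):
        arr = np.asarray([surviving_fraction(r, pe) for r in recs])
        se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        mean = float(arr.mean())
        points.append(
            SurvivalPoint(
                radiation_dose=dose,
                sf=mean,
                se_sf=se,
                condition=cond,
                n_replicates=int(arr.size),
                below_detection=(mean == 0.0),
                total_colonies=int(sum(r.colonies for r in recs)),
            )
        )
    return points


def classify_bliss(
    sf_r: float,
    sf_c: float,
    sf_observed: float,
    tolerance: float = 0.0,
    radiation_dose: float = float("nan"),
) -> SynergyRow:
    """Classify one radiation dose against the Bliss product SF_R * SF_C.

    ``tolerance`` is a relative band around the product inside which the
    verdict is additivity; the default 0 compares plain numbers with strict
    inequality, matching how published tables are typically read.
    Symmetric in (sf_r, sf_c).
    """
    for name, v in (("sf_r", sf_r), ("sf_c", sf_c), ("sf_observed", sf_observed)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    product = sf_r * sf_c
    if sf_observed < (1.0 - tolerance) * product:
        verdict: Verdict = "synergism"
    elif sf_observed > (1.0 + tolerance) * product:
        verdict = "antagonism"
    else:
        verdict = "additivity"
    return SynergyRow(
        radiation_dose=radiation_dose,
        sf_r=sf_r,
        sf_c=sf_c,
        bliss_product=product,
        sf_observed=sf_observed,
        verdict=verdict,
    )


def infer_drug_sf(bliss_product: float, sf_r: float) -> float:
    """Back out the drug-only SF from a reported product and radiation SF.

    Summary tables sometimes print only SF_R and the product SF_R * SF_C;
    this helper recovers the implied SF_C = product / SF_R for reproducing
    such tables when the drug-only measurement is not printed.
    """
    if sf_r <= 0:
        raise ValueError("sf_r must be positive")
    return bliss_product / sf_r


def fit_lq(points: Iterable[SurvivalPoint]) -> LQParameters:
    """Weighted least-squares linear-quadratic fit through the origin.

    Fits ln SF = -alpha*D - beta*D² on points with sf > 0 (0-SF points are
    below detection and undefined on the log scale).  Points are weighted
    by SF: for Poisson colony counts C the variance of ln SF is ~1/C, which
    is proportional to 1/SF at fixed plating, so low-survival points carry
    proportionally less weight.  Estimates are constrained non-negative.
    """
    usable = [p for p in points if p.sf > 0 and p.radiation_dose > 0]
    doses = np.asarray([p.radiation_dose for p in usable])
    if np.unique(doses).size < 3:
        raise ValueError("need >= 3 positive-dose, positive-SF points")
    sf = np.asarray([p.sf for p in usable])
    counts = np.asarray([p.total_colonies for p in usable], dtype=float)
    if np.all(counts > 0):
        w = np.sqrt(counts)  # Var[ln SF] ~ 1/C for pooled Poisson counts
    else:
        reps = np.asarray([p.n_replicates for p in usable])
        w = np.sqrt(sf * reps)  # same weight up to a constant, equal plating
    y = -np.log(sf)
    design = np.column_stack([doses, doses**2])
    coef, _ = nnls(design * w[:, None], y * w)
    alpha, beta = float(coef[0]), float(coef[1])
    if alpha == 0 and beta == 0:
        # pathological flat input; keep the invariant "not both zero"
        raise ValueError("degenerate fit: alpha = beta = 0")
    return LQParameters(alpha=alpha, beta=beta)


def lq_survival(dose: float | np.ndarray, params: LQParameters) -> float | np.ndarray:
    """Evaluate the LQ model SF(D) = exp(-alpha*D - beta*D²)."""
    d = np.asarray(dose, dtype=float)
    sf = np.exp(-params.alpha * d - params.beta * d**2)
    return sf if np.ndim(dose) else float(sf)


def doubling_time(
    series: CellCountSeries, window: tuple[int, int]
) -> float:
    """Doubling time (hours) over an exponential-phase index window.

    T_d = (t - t0) * ln 2 / (ln N - ln N0) for the window endpoints; the
    caller chooses indices inside the exponential phase.
    """
    i0, i1 = window
    t0, t = series.times[i0], series.times[i1]
    n0, n = series.counts[i0], series.counts[i1]
    if t <= t0:
        raise ValueError("window must be forward in time")
    if n <= n0:
        raise ValueError("counts must increase over the window")
    return (t - t0) * math.log(2) / (math.log(n) - math.log(n0))
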