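"""Seedable synthetic-data generators for every assay in the pipeline.

Each generator emulates one assay design with known ground truth, so that
parameter-recovery and calibration properties of the analysis chain can be
tested end to end:

* **clonogenic** — true survival follows the linear-quadratic model
  SF(D) = exp(-alpha*D - beta*D²); the drug multiplies survival by
  ``drug_sf`` and the combination deviates from the Bliss product by the
  multiplicative ``interaction`` (1 = Bliss-null, < 1 = synergy).  Colony
  counts are Poisson.
* **viability plate** — true viability follows a four-parameter logistic;
  absorbance pairs are constructed by fixing the negative-control and
  600 nm baselines and inverting the viability equation for the 570 nm
  channel, so the noiseless plate reproduces the logistic exactly.
* **tumor growth** — per-animal Gompertz trajectories
  V(t) = v0 * exp((a/b)(1 - e^(-b t))) with group-specific multipliers on
  the growth rate ``a``; the combination multiplier is derived so that at
  the evaluation day the expected volume inhibition is Bliss-consistent
  (scaled by ``interaction``).  Measurement noise is multiplicative
  lognormal; caliper triplets factor the volume at fixed, slightly
  perturbed aspect ratios.
* **cohort** — spleen indices, lymphocyte subsets, cytokines and serum
  biochemistry drawn from per-group normal distributions truncated at 0.

A single integer seed drives one named pseudo-random stream per assay, so
adding draws to one simulator never perturbs another's output.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .assay_io import AnimalRecord, CaliperMeasurement, ClonogenicRecord, ViabilityWell
from .growth import TumorTrajectory
from .viability import four_pl

__all__ = [
    "GompertzParams",
    "SimulationConfig",
    "simulate_clonogenic",
    "simulate_viability_plate",
    "simulate_tumor_growth",
    "caliper_table",
    "simulate_cohort",
    "gompertz_volume",
]

# Per-assay stream identifiers mixed with the user seed.
_STREAMS = {"clonogenic": 1, "viability": 2, "growth": 3, "cohort": 4}


def _rng(seed: int, assay: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[assay], seed])


class GompertzParams(BaseModel):
    """Gompertz growth law V(t) = v0 * exp((a/b)(1 - e^(-b t))).

    ``v0`` is the volume at treatment start (mm³), ``a`` the initial
    specific growth rate (1/day) and ``b`` the rate of its exponential
    slow-down (1/day); the plateau is v0 * exp(a/b).
    """

    model_config = ConfigDict(frozen=True)

    v0: float = Field(default=100.0, gt=0)
    a: float = Field(default=0.2124, gt=0)
    b: float = Field(default=0.05, gt=0)


class SimulationConfig(BaseModel):
    """All generator parameters, with defaults matching the emulated study.

    Defaults: 5-dose clonogenic design ({0,2,4,6,8} Gy × {0, 75} µM,
    triplicate, 500 cells per dish, PE 0.5, drug-only SF 0.5); a 7-dose
    viability panel with logistic midpoint 75 µM; five animal arms of six
    mice measured twice weekly for 26 days, with single-agent growth
    multipliers whose expected day-26 volumes reproduce control 2200,
    drug-alone 1500 and radiation-alone 1000 mm³; ``interaction`` defaults
    to 1 (Bliss-null), the reference condition for calibration.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0

    # clonogenic assay
    lq_alpha: float = Field(default=0.3, ge=0, description="1/Gy")
    lq_beta: float = Field(default=0.03, ge=0, description="1/Gy²")
    drug_sf: float = Field(default=0.5, gt=0, le=1)
    interaction: float = Field(
        default=1.0,
        gt=0,
        description="multiplicative deviation from Bliss (1 = null, <1 = synergy)",
    )
    pe: float = Field(default=0.5, gt=0, le=1)
    n_plated: int = Field(default=500, gt=0)
    n_plated_by_dose: Mapping[float, int] | None = Field(
        default={0.0: 500, 2.0: 500, 4.0: 2000, 6.0: 10000, 8.0: 50000},
        description=(
            "dose-escalated plating, standard practice to keep colony "
            "counts countable across the SF range the assay must resolve; "
            "None uses n_plated at every dose"
        ),
    )
    radiation_doses_gy: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    drug_dose_um: float = Field(default=75.0, gt=0)
    n_replicates: int = Field(default=3, ge=1)

    # viability assay
    viability_doses_um: tuple[float, ...] = (0.0, 1.0, 20.0, 50.0, 75.0, 85.0, 100.0)
    viability_4pl: tuple[float, float, float, float] = Field(
        default=(100.0, 0.0, 75.0, 2.0),
        description="(top %, bottom %, midpoint µM, Hill slope)",
    )
    wells_per_dose: int = Field(default=3, ge=1)
    n_negative_controls: int = Field(default=2, ge=1)
    absorbance_noise_sd: float = Field(default=0.01, ge=0)
    negctrl_a570: float = Field(default=0.05, gt=0)
    negctrl_a600: float = Field(default=0.2, gt=0)
    test_a600: float = Field(default=0.1, gt=0)

    # tumor growth
    gompertz: GompertzParams = GompertzParams()
    growth_multipliers: Mapping[str, float] = Field(
        default={"control": 1.0, "drug": 0.8761, "radiation": 0.7449},
    )
    volume_noise_cv: float = Field(default=0.2, ge=0)
    n_animals: int = Field(default=6, ge=1)
    measurement_days: tuple[float, ...] = (
        0.0, 3.0, 7.0, 10.0, 14.0, 17.0, 21.0, 24.0, 26.0,
    )
    evaluation_day: float = Field(default=26.0, ge=0)
    aspect_ratios: tuple[float, float, float] = (1.0, 0.8, 0.6)
    aspect_jitter: float = Field(default=0.1, ge=0)
    volume_constant: float = Field(default=0.523, gt=0)

    # cohort
    cohort_means: Mapping[str, Mapping[str, float]] = Field(
        default={
            "spleen_index": {
                "normal": 0.0040, "control": 0.0052, "radiation": 0.0044,
                "drug": 0.0048, "combination": 0.0050,
            },
            "CD4_percent": {
                "normal": 24.1, "control": 13.6, "radiation": 18.6,
                "drug": 21.9, "combination": 24.8,
            },
            "CD8_percent": {
                "normal": 17.1, "control": 11.5, "radiation": 13.6,
                "drug": 17.8, "combination": 20.5,
            },
            "IL12": {
                "normal": 50.0, "control": 30.0, "radiation": 40.0,
                "drug": 45.0, "combination": 60.0,
            },
            "IL18": {
                "normal": 120.0, "control": 80.0, "radiation": 100.0,
                "drug": 110.0, "combination": 150.0,
            },
            "IFNg": {
                "normal": 15.0, "control": 8.0, "radiation": 11.0,
                "drug": 13.0, "combination": 20.0,
            },
        }
    )
    cohort_sds: Mapping[str, float] = Field(
        default={
            "spleen_index": 0.0005, "CD4_percent": 2.5, "CD8_percent": 2.0,
            "IL12": 8.0, "IL18": 20.0, "IFNg": 3.0,
        }
    )
    body_weight_mean_g: float = Field(default=22.0, gt=0)
    body_weight_sd_g: float = Field(default=1.5, ge=0)
    biochem_means: Mapping[str, float] = Field(
        default={"alp": 163.0, "alb": 2.3, "alt": 46.0, "ast": 251.0,
                 "bun": 33.0, "cre": 0.5}
    )
    biochem_cv: float = Field(default=0.15, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.lq_alpha == 0 and self.lq_beta == 0:
            raise ValueError("lq_alpha and lq_beta cannot both be zero")
        if "control" not in self.growth_multipliers:
            raise ValueError("growth_multipliers must include control")
        for name, sd in self.cohort_sds.items():
            if sd < 0:
                raise ValueError(f"negative sd for {name}")
        return self


def _true_sf(config: SimulationConfig, dose_gy: float, drug: bool) -> float:
    sf = math.exp(-config.lq_alpha * dose_gy - config.lq_beta * dose_gy**2)
    if drug:
        sf *= config.drug_sf
        if dose_gy > 0:
            sf *= config.interaction
    return sf


def simulate_clonogenic(
    config: SimulationConfig, noiseless: bool = False
) -> list[ClonogenicRecord]:
    """Simulate a clonogenic assay over the full dose × drug design.

    Colony counts are Poisson with mean ``n_plated * pe * true SF``; with
    ``noiseless=True`` the expectation is rounded to the nearest count
    instead of sampled.
    """
    rng = _rng(config.seed, "clonogenic")
    records = []
    for drug in (False, True):
        for dose in config.radiation_doses_gy:
            plated = config.n_plated
            if config.n_plated_by_dose is not None:
                plated = int(config.n_plated_by_dose.get(dose, plated))
            mean = plated * config.pe * _true_sf(config, dose, drug)
            if mean > plated:
                raise ValueError(
                    "expected colony count exceeds cells plated; "
                    "check pe/interaction configuration"
                )
            for rep in range(config.n_replicates):
                colonies = (
                    int(round(mean)) if noiseless else int(rng.poisson(mean))
                )
                records.append(
                    ClonogenicRecord(
                        radiation_gy=dose,
                        drug_um=config.drug_dose_um if drug else 0.0,
                        cells_plated=plated,
                        colonies=min(colonies, plated),
                        replicate=rep,
                    )
                )
    return records


def _invert_viability_for_a570(
    viability: float, config: SimulationConfig
) -> float:
    """Solve the viability equation for A1 given fixed A2 and controls."""
    from .assay_io import VIABILITY_COEFFICIENTS

    c1, c2, c3, c4 = VIABILITY_COEFFICIENTS
    denominator = c3 * config.negctrl_a600 - c4 * config.negctrl_a570
    return (viability / 100.0 * denominator + c2 * config.test_a600) / c1


def simulate_viability_plate(
    config: SimulationConfig, noiseless: bool = False
) -> list[ViabilityWell]:
    """Simulate one alamarBlue plate from the configured 4PL truth.

    The noiseless plate passed through ``build_curve`` reproduces the 4PL
    values exactly (inverse construction); noise is Gaussian on every
    absorbance channel of the test wells.
    """
    rng = _rng(config.seed, "viability")
    top, bottom, ic50, hill = config.viability_4pl
    wells = []
    for i in range(config.n_negative_controls):
        wells.append(
            ViabilityWell(
                well_id=f"NC{i + 1}",
                dose=0.0,
                a570=config.negctrl_a570,
                a600=config.negctrl_a600,
                is_negative_control=True,
            )
        )
    for dose in config.viability_doses_um:
        true_v = four_pl(dose, top, bottom, ic50, hill)
        a570 = _invert_viability_for_a570(true_v, config)
        for rep in range(config.wells_per_dose):
            noise570 = 0.0 if noiseless else rng.normal(0, config.absorbance_noise_sd)
            noise600 = 0.0 if noiseless else rng.normal(0, config.absorbance_noise_sd)
            wells.append(
                ViabilityWell(
                    well_id=f"D{dose:g}R{rep + 1}",
                    dose=dose,
                    a570=a570 + noise570,
                    a600=config.test_a600 + noise600,
                    is_negative_control=False,
                )
            )
    return wells


def gompertz_volume(
    t: float | np.ndarray, params: GompertzParams, multiplier: float = 1.0
) -> float | np.ndarray:
    """Gompertz volume at time t with a multiplier on the growth rate a."""
    a = params.a * multiplier
    v = params.v0 * np.exp((a / params.b) * (1.0 - np.exp(-params.b * np.asarray(t))))
    return v if np.ndim(t) else float(v)


def _combination_multiplier(config: SimulationConfig) -> float:
    """Growth-rate multiplier giving a Bliss-consistent combination arm.

    The expected combination volume at the evaluation day is
    V_ctrl * (V_drug/V_ctrl) * (V_rad/V_ctrl) * interaction — the Bliss
    product of the single-agent volume fractions, scaled by the interaction
    factor — and the multiplier is solved from the Gompertz law.
    """
    gp = config.gompertz
    t = config.evaluation_day
    shape = (gp.a / gp.b) * (1.0 - math.exp(-gp.b * t))
    v = {
        g: gompertz_volume(t, gp, m)
        for g, m in config.growth_multipliers.items()
    }
    v_ctrl = v["control"]
    target = (
        v_ctrl
        * (v["drug"] / v_ctrl)
        * (v["radiation"] / v_ctrl)
        * config.interaction
    )
    if target <= 0:
        raise ValueError("combination target volume must be positive")
    return math.log(target / gp.v0) / shape


def simulate_tumor_growth(
    config: SimulationConfig, noiseless: bool = False
) -> list[TumorTrajectory]:
    """Simulate per-animal tumor trajectories for the four tumor-bearing arms.

    Measurement noise is multiplicative lognormal with coefficient of
    variation ``volume_noise_cv``, mean-preserving (E[measured] = true).
    """
    rng = _rng(config.seed, "growth")
    multipliers = dict(config.growth_multipliers)
    if {"drug", "radiation"} <= multipliers.keys():
        multipliers.setdefault("combination", _combination_multiplier(config))
    days = np.asarray(config.measurement_days)
    sigma = math.sqrt(math.log(1.0 + config.volume_noise_cv**2))

    trajectories = []
    for group, mult in multipliers.items():
        true_vols = gompertz_volume(days, config.gompertz, mult)
        for i in range(config.n_animals):
            if noiseless or sigma == 0:
                vols = true_vols
            else:
                noise = rng.normal(-sigma**2 / 2.0, sigma, size=days.size)
                vols = true_vols * np.exp(noise)
            trajectories.append(
                TumorTrajectory(
                    animal_id=f"{group}-{i + 1:02d}",
                    group=group,
                    days=tuple(float(d) for d in days),
                    volumes_mm3=tuple(float(v) for v in vols),
                )
            )
    return trajectories


def caliper_table(
    trajectories: Sequence[TumorTrajectory],
    config: SimulationConfig,
) -> list[CaliperMeasurement]:
    """Render trajectories as caliper triplets with realistic aspect ratios.

    Each volume is factored into L >= W >= H at the configured aspect
    ratios, jittered by ±``aspect_jitter``; recomputing
    ``constant * L * W * H`` recovers the volume exactly.
    """
    rng = _rng(config.seed, "growth")
    rng = np.random.default_rng(rng.integers(2**31))  # sub-stream
    rows = []
    r1, r2, r3 = config.aspect_ratios
    for traj in trajectories:
        for day, vol in zip(traj.days, traj.volumes_mm3):
            j = config.aspect_jitter
            p = (r2 / r1) * (1.0 + rng.uniform(-j, j))
            q = (r3 / r1) * (1.0 + rng.uniform(-j, j))
            length = (vol / (config.volume_constant * p * q)) ** (1.0 / 3.0)
            rows.append(
                CaliperMeasurement(
                    animal_id=traj.animal_id,
                    group=traj.group,
                    day=day,
                    length_mm=length,
                    width_mm=p * length,
                    height_mm=q * length,
                )
            )
    return rows


def simulate_cohort(
    config: SimulationConfig, noiseless: bool = False
) -> tuple[list[AnimalRecord], dict[str, dict[str, np.ndarray]]]:
    """Simulate terminal animal records and per-animal measurements.

    Returns ``(animal records, measurements)`` where measurements maps
    analyte -> group -> per-animal values (normal distributions truncated
    at 0; exact group means when ``noiseless``).
    """
    rng = _rng(config.seed, "cohort")
    groups = list(config.cohort_means["spleen_index"].keys())

    measurements: dict[str, dict[str, np.ndarray]] = {}
    for analyte, means in config.cohort_means.items():
        sd = config.cohort_sds.get(analyte, 0.0)
        measurements[analyte] = {}
        for group in groups:
            mean = means[group]
            if noiseless or sd == 0:
                vals = np.full(config.n_animals, mean)
            else:
                vals = rng.normal(mean, sd, size=config.n_animals)
                vals = np.clip(vals, 0.0, None)
            measurements[analyte][group] = vals

    animals = []
    for group in groups:
        spleen_idx = measurements["spleen_index"][group]
        for i in range(config.n_animals):
            body = (
                config.body_weight_mean_g
                if noiseless or config.body_weight_sd_g == 0
                else max(
                    rng.normal(config.body_weight_mean_g, config.body_weight_sd_g),
                    1.0,
                )
            )
            biochem = {}
            for analyte, mean in config.biochem_means.items():
                if noiseless or config.biochem_cv == 0:
                    biochem[analyte] = mean
                else:
                    biochem[analyte] = max(
                        rng.normal(mean, config.biochem_cv * mean), 0.0
                    )
            animals.append(
                AnimalRecord(
                    animal_id=f"{group}-{i + 1:02d}",
                    group=group,
                    body_weight_g=body,
                    spleen_weight_g=float(spleen_idx[i]) * body,
                    biochem=biochem,
                )
            )
    return animals, measurements
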