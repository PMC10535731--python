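"""alamarBlue viability analysis: absorbance pairs -> % viability -> IC50.

The viability of a test well is computed from its absorbances at 570 nm (A1)
and 600 nm (A2) against a cell-free negative control (N1 at 570 nm, N2 at
600 nm) with the manufacturer's linear combination

    viability % = 100 * (c1*A1 - c2*A2) / (c3*N2 - c4*N1),

c = (117216, 80586, 155677, 14652).  The raw scale is preserved: values may
exceed 100% or fall below 0%; clipping is a display concern only.

IC50 is estimated either by log-linear interpolation of the first downward
crossing of 50% (``log_interp``) or by a constrained four-parameter logistic
fit (``four_pl``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .assay_io import VIABILITY_COEFFICIENTS, ViabilityWell

__all__ = [
    "DoseViabilityCurve",
    "DegenerateControlError",
    "NotEstimableError",
    "FitError",
    "compute_viability",
    "build_curve",
    "estimate_ic50",
    "four_pl",
]


class DegenerateControlError(ValueError):
    """Negative-control absorbances make the viability denominator ~0."""


class NotEstimableError(ValueError):
    """The dose-viability curve never crosses 50%."""


class FitError(RuntimeError):
    """The 4PL least-squares fit failed to converge."""


@dataclass(frozen=True)
class DoseViabilityCurve:
    """Per-dose viability summary of one plate.

    Doses are strictly increasing (µM); ``se_viability`` is the standard
    error of the mean per dose (NaN where only one replicate exists).
    """

    doses: tuple[float, ...]
    mean_viability: tuple[float, ...]
    se_viability: tuple[float, ...]
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses)
        if d.size < 2 or not np.all(np.diff(d) > 0):
            raise ValueError("doses must be >= 2 and strictly increasing")
        if not np.all(np.isfinite(self.mean_viability)):
            raise ValueError("viabilities must be finite")
        if any(k < 1 for k in self.n):
            raise ValueError("each dose needs at least one replicate")


def compute_viability(
    a570_test: float,
    a600_test: float,
    a570_negctrl: float,
    a600_negctrl: float,
    coefficients: Sequence[float] = VIABILITY_COEFFICIENTS,
) -> float:
    """Percent viability of a test well relative to the cell-free control.

    Linear in (A1, A2) for fixed controls; not clipped to [0, 100].

    Raises
    ------
    DegenerateControlError
        If the control combination c3*N2 - c4*N1 is (near) zero.
    """
    c1, c2, c3, c4 = coefficients
    denominator = c3 * a600_negctrl - c4 * a570_negctrl
    scale = abs(c3 * a600_negctrl) + abs(c4 * a570_negctrl)
    if abs(denominator) <= max(scale, 1.0) * 1e-12:
        raise DegenerateControlError(
            f"degenerate negative control: c3*N2 - c4*N1 = {denominator!r}"
        )
    return 100.0 * (c1 * a570_test - c2 * a600_test) / denominator


def build_curve(
    wells: Iterable[ViabilityWell],
    coefficients: Sequence[float] = VIABILITY_COEFFICIENTS,
) -> DoseViabilityCurve:
    """Summarize a plate of wells into a dose-viability curve.

    Negative-control absorbances are averaged into a single (N1, N2) anchor;
    each test well's viability is computed against it, then averaged per
    dose.  Requires at least one negative-control well and two distinct
    doses.
    """
    wells = list(wells)
    controls = [w for w in wells if w.is_negative_control]
    tests = [w for w in wells if not w.is_negative_control]
    if not controls:
        raise ValueError("plate has no negative-control well")
    n1 = float(np.mean([w.a570 for w in controls]))
    n2 = float(np.mean([w.a600 for w in controls]))

    by_dose: dict[float, list[float]] = {}
    for w in tests:
        v = compute_viability(w.a570, w.a600, n1, n2, coefficients)
        by_dose.setdefault(w.dose, []).append(v)
    if len(by_dose) < 2:
        raise ValueError("need at least two distinct doses to build a curve")

    doses = sorted(by_dose)
    means, ses, ns = [], [], []
    for d in doses:
        vals = np.asarray(by_dose[d], dtype=float)
        means.append(float(vals.mean()))
        ses.append(
            float(vals.std(ddof=1) / math.sqrt(vals.size))
            if vals.size > 1
            else float("nan")
        )
        ns.append(int(vals.size))
    return DoseViabilityCurve(
        doses=tuple(doses),
        mean_viability=tuple(means),
        se_viability=tuple(ses),
        n=tuple(ns),
    )


def four_pl(
    dose: np.ndarray | float,
    top: float,
    bottom: float,
    ic50: float,
    hill: float,
) -> np.ndarray | float:
    """Four-parameter logistic: decreasing viability with dose."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        val = bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)
    return val if np.ndim(dose) else float(val)


def _log_interp_ic50(curve: DoseViabilityCurve) -> float:
    # dose 0 cannot enter log-space interpolation
    pairs = [
        (d, v)
        for d, v in zip(curve.doses, curve.mean_viability)
        if d > 0
    ]
    if len(pairs) < 2:
        raise NotEstimableError("need >= 2 positive doses for interpolation")
    for (d_lo, v_lo), (d_hi, v_hi) in zip(pairs, pairs[1:]):
        if v_lo == 50.0:
            return d_lo
        if v_lo > 50.0 >= v_hi:
            frac = (v_lo - 50.0) / (v_lo - v_hi)
            log_d = math.log10(d_lo) + frac * (
                math.log10(d_hi) - math.log10(d_lo)
            )
            return 10.0 ** log_d
    if pairs[-1][1] == 50.0:
        return pairs[-1][0]
    raise NotEstimableError(
        "viability never crosses 50% within the dose range"
    )


def _four_pl_ic50(curve: DoseViabilityCurve) -> float:
    doses = np.asarray(curve.doses, dtype=float)
    viab = np.asarray(curve.mean_viability, dtype=float)
    if doses.size < 4:
        raise ValueError("4PL fit needs at least 4 doses")

    # Constrained fit: top in [80, 120]%, bottom in [0, 50]%, hill > 0.
    # These bounds keep 7-point curves away from degenerate optima.
    try:
        ic50_init = _log_interp_ic50(curve)
    except NotEstimableError:
        positive = doses[doses > 0]
        ic50_init = float(np.exp(np.mean(np.log(positive))))
    p0 = [
        float(np.clip(viab.max(), 80.0, 120.0)),
        float(np.clip(viab.min(), 0.0, 50.0)),
        ic50_init,
        1.0,
    ]
    bounds = ([80.0, 0.0, 1e-9, 1e-9], [120.0, 50.0, np.inf, np.inf])
    try:
        popt, _ = curve_fit(
            four_pl, doses, viab, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message varies
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    return float(popt[2])


def estimate_ic50(
    curve: DoseViabilityCurve,
    method: Literal["log_interp", "four_pl"] = "log_interp",
) -> float:
    """Estimate the 50%-viability concentration (µM) from a curve.

    ``log_interp`` locates the first downward crossing of 50% by linear
    interpolation of viability against log10(dose); ``four_pl`` returns the
    midpoint parameter of a constrained 4-parameter logistic least-squares
    fit.
    """
    if method == "log_interp":
        return _log_interp_ic50(curve)
    if method == "four_pl":
        return _four_pl_ic50(curve)
    raise ValueError(f"unknown method {method!r}")
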