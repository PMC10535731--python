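"""Surviving fractions, Bliss multiplicativity verdicts, LQ fit, doubling time."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radsyn.assay_io import ClonogenicRecord
from radsyn.clonogenic import (
    CellCountSeries,
    SurvivalPoint,
    classify_bliss,
    doubling_time,
    fit_lq,
    infer_drug_sf,
    lq_survival,
    plating_efficiency,
    survival_points,
    surviving_fraction,
)
from radsyn.simulate import SimulationConfig, simulate_clonogenic


def _rec(gy=0.0, um=0.0, plated=100, colonies=50, rep=0):
    return ClonogenicRecord(
        radiation_gy=gy, drug_um=um, cells_plated=plated, colonies=colonies,
        replicate=rep,
    )


class TestPlatingEfficiency:
    def test_direct_ratio(self):
        assert plating_efficiency([_rec(colonies=50, plated=100)]) == 0.5

    def test_replicates_pooled_as_ratio_of_totals(self):
        recs = [
            _rec(plated=200, colonies=90, rep=0),
            _rec(plated=200, colonies=110, rep=1),
        ]
        assert plating_efficiency(recs) == 200 / 400

    def test_zero_colonies_everywhere_is_error(self):
        with pytest.raises(ValueError, match="zero colonies"):
            plating_efficiency([_rec(colonies=0)])

    def test_no_untreated_record_is_error(self):
        with pytest.raises(ValueError, match="untreated"):
            plating_efficiency([_rec(gy=2.0, colonies=10)])


class TestSurvivingFraction:
    def test_definition(self):
        # colonies = plated * pe -> sf = 1
        assert surviving_fraction(_rec(colonies=50, plated=100), pe=0.5) == 1.0

    def test_hand_value(self):
        assert surviving_fraction(
            _rec(gy=4, colonies=26, plated=200), pe=0.5
        ) == pytest.approx(0.26)

    def test_nonpositive_pe_rejected(self):
        with pytest.raises(ValueError):
            surviving_fraction(_rec(), pe=0.0)

    def test_untreated_sf_with_own_pe_is_one(self):
        """SF at (0 Gy, 0 µM) with the PE from the same records equals 1."""
        recs = [
            _rec(plated=200, colonies=90, rep=0),
            _rec(plated=200, colonies=110, rep=1),
            _rec(gy=4, plated=200, colonies=26),
        ]
        pe = plating_efficiency(recs)
        points = survival_points(recs, pe)
        untreated = [p for p in points if p.condition == "untreated"][0]
        assert math.isclose(untreated.sf, 1.0, abs_tol=1e-12)

    def test_zero_colonies_flagged_below_detection(self):
        recs = [_rec(colonies=50), _rec(gy=8, colonies=0)]
        points = survival_points(recs)
        p8 = [p for p in points if p.radiation_dose == 8][0]
        assert p8.sf == 0.0 and p8.below_detection


class TestClassifyBliss:
    @pytest.mark.parametrize(
        "sf_r, sf_c, observed, product",
        [
            (0.74, 0.5, 0.36, 0.37),
            (0.26, 0.5, 0.06, 0.13),
            (0.03, 0.5, 4e-3, 0.015),
            (3e-3, 0.5, 3.5e-4, 1.5e-3),
        ],
    )
    def test_synergy_rows_with_inferred_drug_sf(self, sf_r, sf_c, observed, product):
        row = classify_bliss(sf_r, sf_c, observed)
        assert row.bliss_product == pytest.approx(product, rel=1e-12)
        assert row.verdict == "synergism"

    def test_inferred_drug_sf_consistent_across_rows(self):
        for sf_r, product in [(0.74, 0.37), (0.26, 0.13), (0.03, 0.015), (3e-3, 1.5e-3)]:
            assert infer_drug_sf(product, sf_r) == pytest.approx(0.5, rel=1e-12)

    def test_observed_equal_to_product_is_additive(self):
        assert classify_bliss(0.5, 0.4, 0.2).verdict == "additivity"

    def test_observed_above_product_is_antagonism(self):
        assert classify_bliss(0.5, 0.5, 0.30).verdict == "antagonism"

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            classify_bliss(0.0, 0.5, 0.1)

    @given(
        sf_r=st.floats(1e-6, 1.0),
        sf_c=st.floats(1e-6, 1.0),
        obs=st.floats(1e-6, 1.0),
        tol=st.floats(0, 0.5),
    )
    def test_symmetry_in_single_agent_fractions(self, sf_r, sf_c, obs, tol):
        a = classify_bliss(sf_r, sf_c, obs, tol)
        b = classify_bliss(sf_c, sf_r, obs, tol)
        assert a.verdict == b.verdict
        assert a.bliss_product == pytest.approx(b.bliss_product, rel=1e-12)


class TestFitLQ:
    @staticmethod
    def _points(alpha, beta, doses=(2, 4, 6, 8)):
        return [
            SurvivalPoint(
                radiation_dose=d,
                sf=math.exp(-alpha * d - beta * d * d),
                se_sf=0.0,
                condition="radiation_only",
            )
            for d in doses
        ]

    def test_noiseless_recovery_is_exact(self):
        params = fit_lq(self._points(0.3, 0.03))
        assert params.alpha == pytest.approx(0.3, abs=1e-10)
        assert params.beta == pytest.approx(0.03, abs=1e-10)
        # oracle equivalence: LQ evaluation reproduces the inputs
        for p in self._points(0.3, 0.03):
            assert lq_survival(p.radiation_dose, params) == pytest.approx(
                p.sf, rel=1e-9
            )

    def test_pure_exponential_gives_zero_beta(self):
        params = fit_lq(self._points(0.3, 0.0))
        assert params.beta == pytest.approx(0.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_lq(self._points(0.3, 0.03, doses=(2, 4)))

    def test_alpha_recovery_under_poisson_noise(self):
        """alpha within ±20% of truth in >= 90% of 200 simulated assays."""
        hits = 0
        for seed in range(200):
            cfg = SimulationConfig(seed=seed)
            recs = simulate_clonogenic(cfg)
            pe = plating_efficiency(recs)
            pts = [
                p
                for p in survival_points(recs, pe)
                if p.condition == "radiation_only"
            ]
            est = fit_lq(pts)
            hits += abs(est.alpha - cfg.lq_alpha) <= 0.2 * cfg.lq_alpha
        assert hits / 200 >= 0.90


class TestDoublingTime:
    def test_doubling_over_window_equals_elapsed_time(self):
        series = CellCountSeries(times=(12.0, 48.0), counts=(1e5, 2e5))
        assert doubling_time(series, (0, 1)) == pytest.approx(36.0)

    def test_hand_value_three_doublings(self):
        series = CellCountSeries(times=(12.0, 48.0), counts=(1e5, 8e5))
        # 36 * ln2 / ln8 = 12
        assert doubling_time(series, (0, 1)) == pytest.approx(12.0)

    def test_flat_counts_rejected(self):
        series = CellCountSeries(times=(12.0, 48.0), counts=(1e5, 1e5))
        with pytest.raises(ValueError, match="increase"):
            doubling_time(series, (0, 1))
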