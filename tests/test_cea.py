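"""CEA engine: incremental summaries, bootstrap, CEAC, NMB, sensitivity."""

import numpy as np
import pandas as pd
import pytest

import rwcea
from rwcea.cea import (
    BootstrapResult,
    CEAEngine,
    bootstrap_cea,
    ceac,
    incremental_summary,
    nmb_regression,
    price_reduction_curve,
    discount_sensitivity,
)
from rwcea.config import UtilityParams
from rwcea.exceptions import ValidationError
from tests.conftest import make_cohort


def _adjusted_frame(arm, ly, cost, qaly=None):
    n = len(arm)
    df = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "arm": arm,
        "ly": np.asarray(ly, float),
        "qaly": np.asarray(qaly if qaly is not None else ly, float),
        "cost_total": np.asarray(cost, float),
        "cost_drug_of_interest": 0.0,
    })
    for cat in rwcea.COST_CATEGORIES:
        df[f"cost_{cat}"] = 0.0
    return df


def _dominance_fixture():
    """Every treated patient strictly costlier and longer-lived than every
    control patient; no censoring, so all bootstrap resamples are NE."""
    n = 6
    fu = np.r_[np.full(n, 200.0), np.full(n, 900.0)]
    death = np.ones(2 * n, int)
    arm = ["control"] * n + ["treated"] * n
    coh = make_cohort(fu, death, arm, covariate=np.tile([0.0, 1.0, 2.0], 4))
    cost = np.zeros((2 * n, 61))
    cost[:n, 0] = 10_000.0
    cost[n:, 0] = 80_000.0
    mats = {"systemic_therapy": cost}
    return coh, mats


ENGINE_OPTS = dict(propensity_covariates=("x",),
                   utility_params=UtilityParams())


class TestIncrementalSummary:
    def test_treated_minus_control_contrast(self):
        adj = _adjusted_frame(["control", "treated"], [0.70, 1.29],
                              [65_670.0, 156_903.0], qaly=[0.48, 0.88])
        res = incremental_summary(adj, np.ones(2))
        assert res.incremental_ly == pytest.approx(0.59)
        assert res.incremental_cost == pytest.approx(91_233.0)
        assert res.incremental_qaly == pytest.approx(0.40)
        assert res.icer_per_ly == pytest.approx(91_233.0 / 0.59)

    def test_zero_effect_reports_undefined_icer(self):
        adj = _adjusted_frame(["control", "treated"], [1.0, 1.0], [0.0, 100.0])
        res = incremental_summary(adj, np.ones(2))
        assert res.icer_per_ly is None

    def test_weighted_means_respect_weights(self):
        adj = _adjusted_frame(["control", "control", "treated"],
                              [1.0, 3.0, 2.0], [0.0, 0.0, 0.0])
        res = incremental_summary(adj, np.array([3.0, 1.0, 1.0]))
        assert res.arm_means["ly"]["control"] == pytest.approx(1.5)


class TestBootstrap:
    def test_resampling_disabled_reproduces_point_estimate(self):
        coh, mats = _dominance_fixture()
        boot = bootstrap_cea(coh, mats, B=3, seed=1, resample=False,
                             **ENGINE_OPTS)
        assert np.all(boot.dc == boot.point.incremental_cost)
        assert np.all(boot.de_ly == boot.point.incremental_ly)

    def test_zero_variance_fixture_replicates_equal_point(self):
        coh, mats = _dominance_fixture()
        opts = dict(ENGINE_OPTS,
                    utility_params=UtilityParams(pf_sd=1e-6, disutility_sd=1e-6))
        boot = bootstrap_cea(coh, mats, B=20, seed=2, **opts)
        np.testing.assert_allclose(boot.dc, boot.point.incremental_cost,
                                   rtol=1e-9)
        np.testing.assert_allclose(boot.de_ly, boot.point.incremental_ly,
                                   rtol=1e-9)

    def test_dominance_puts_all_replicates_north_east(self):
        coh, mats = _dominance_fixture()
        boot = bootstrap_cea(coh, mats, B=50, seed=3, **ENGINE_OPTS)
        counts = boot.quadrant_counts("ly")
        assert counts["NE"] == 50
        assert sum(counts.values()) == boot.B

    def test_percentile_ci_brackets_replicates(self, small_sim):
        cfg, cohort, mats = small_sim
        boot = bootstrap_cea(cohort, mats, B=60, seed=4)
        lo, hi = boot.point.ci["incremental_cost"]
        assert lo < np.median(boot.dc) < hi
        icer_ci = boot.point.ci["icer_per_ly"]
        if np.all(boot.de_ly > 0):
            assert icer_ci is not None and icer_ci[0] < icer_ci[1]

    def test_icer_ci_undefined_when_effect_changes_sign(self):
        point = None
        dc = np.array([1.0, 2.0, 3.0, 4.0])
        de = np.array([-0.1, 0.1, 0.2, 0.3])
        boot = BootstrapResult(B=4, dc=dc, de_ly=de, de_qaly=de, seed=0,
                               n_redrawn=0, point=incremental_summary(
                                   _adjusted_frame(["control", "treated"],
                                                   [1.0, 2.0], [0.0, 1.0]),
                                   np.ones(2)))
        assert boot.icer_ci("ly") is None


class TestCeac:
    def test_enumeration_oracle(self):
        adj = incremental_summary(_adjusted_frame(["control", "treated"],
                                                  [1.0, 2.0], [0.0, 100.0]),
                                  np.ones(2))
        boot = BootstrapResult(B=2, dc=np.array([100.0, 300.0]),
                               de_ly=np.array([1.0, 1.0]),
                               de_qaly=np.array([1.0, 1.0]),
                               seed=0, n_redrawn=0, point=adj)
        curve = ceac(boot, wtp_grid=[0.0, 200.0, 1e7], effect_measure="ly")
        np.testing.assert_allclose(curve.probability, [0.0, 0.5, 1.0])

    def test_nondecreasing_when_effects_positive_and_matches_oracle(self, small_sim):
        cfg, cohort, mats = small_sim
        boot = bootstrap_cea(cohort, mats, B=40, seed=5)
        grid = np.arange(0, 300_001, 5000, dtype=float)
        curve = ceac(boot, grid)
        if np.all(boot.de_ly > 0):
            assert np.all(np.diff(curve.probability) >= 0)
        # independent replicate-enumeration oracle
        for lam, p in zip(grid[::12], curve.probability[::12]):
            manual = np.mean(lam * boot.de_ly - boot.dc > 0)
            assert p == manual


class TestNmbRegression:
    def test_wtp_zero_equals_minus_incremental_cost(self):
        adj = _adjusted_frame(["control", "treated", "control", "treated"],
                              [0.5, 1.0, 0.5, 1.0],
                              [20_000.0, 50_000.0, 20_000.0, 50_000.0])
        res = nmb_regression(adj, np.ones(4), 0.0)
        assert res.incremental_nmb == pytest.approx(-30_000.0)

    def test_hand_computed_four_patient_case(self):
        adj = _adjusted_frame(["treated", "treated", "control", "control"],
                              [1.0, 1.0, 0.5, 0.5],
                              [50_000.0, 50_000.0, 20_000.0, 20_000.0])
        res = nmb_regression(adj, np.ones(4), 100_000.0)
        assert res.incremental_nmb == pytest.approx(20_000.0)
        assert res.cost_effective

    def test_affine_in_wtp_with_slope_de_and_intercept_minus_dc(self, small_sim):
        cfg, cohort, mats = small_sim
        engine = CEAEngine(cohort, mats)
        adj = rwcea.adjusted_outcomes(cohort, mats,
                                      utilities=(0.79, 0.55))
        w = engine.base_weights
        point = incremental_summary(adj, w)
        lams = [0.0, 75_000.0, 150_000.0]
        vals = [nmb_regression(adj, w, lam).incremental_nmb for lam in lams]
        for lam, v in zip(lams, vals):
            expect = lam * point.incremental_ly - point.incremental_cost
            assert v == pytest.approx(expect, rel=1e-9, abs=1e-6)

    def test_zero_crossing_at_point_icer(self, small_sim):
        cfg, cohort, mats = small_sim
        adj = rwcea.adjusted_outcomes(cohort, mats, utilities=(0.79, 0.55))
        engine = CEAEngine(cohort, mats)
        w = engine.base_weights
        point = incremental_summary(adj, w)
        res = nmb_regression(adj, w, point.icer_per_ly)
        assert res.incremental_nmb == pytest.approx(0.0, abs=1e-6)

    def test_single_arm_rejected(self):
        adj = _adjusted_frame(["treated", "treated"], [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValidationError):
            nmb_regression(adj, np.ones(2), 1000.0)


class TestSensitivity:
    def test_price_fraction_zero_is_base_case(self, small_sim):
        cfg, cohort, mats = small_sim
        tab = price_reduction_curve(cohort, mats, fractions=[0.0])
        engine = CEAEngine(cohort, mats)
        base = engine.estimate(np.arange(len(cohort)))
        assert tab["icer_per_qaly"].iloc[0] == pytest.approx(base.icer_per_qaly)

    def test_icer_nonincreasing_in_price_reduction(self, small_sim):
        cfg, cohort, mats = small_sim
        tab = price_reduction_curve(cohort, mats,
                                    fractions=np.linspace(0, 1, 6))
        assert (np.diff(tab["icer_per_qaly"]) <= 1e-9).all()
        assert (np.diff(tab["icer_per_ly"]) <= 1e-9).all()

    def test_full_reduction_leaves_residual_incremental_cost(self):
        coh, mats = _dominance_fixture()
        drug = np.zeros((len(coh), 61))
        drug[6:, 0] = 50_000.0
        mats = dict(mats, drug_of_interest=drug)
        tab = price_reduction_curve(coh, mats, fractions=[0.0, 1.0],
                                    discount_rate=0.0, **ENGINE_OPTS)
        # tagged cost removed entirely: what remains is the non-drug excess
        assert tab["incremental_cost"].iloc[1] == pytest.approx(
            tab["incremental_cost"].iloc[0] - 50_000.0)

    def test_missing_drug_tag_rejected(self):
        coh, mats = _dominance_fixture()
        with pytest.raises(ValidationError, match="drug"):
            price_reduction_curve(coh, mats, **ENGINE_OPTS)

    def test_discount_rate_direction_with_front_loaded_costs(self, small_sim):
        cfg, cohort, mats = small_sim
        tab = discount_sensitivity(cohort, mats, rates=(0.0, 0.015, 0.03))
        icers = tab["icer_per_ly"].to_numpy()
        assert icers[0] < icers[1] < icers[2]

    def test_base_rate_row_matches_standalone_estimate(self, small_sim):
        cfg, cohort, mats = small_sim
        tab = discount_sensitivity(cohort, mats, rates=(0.015,))
        engine = CEAEngine(cohort, mats, discount_rate=0.015)
        base = engine.estimate(np.arange(len(cohort)))
        assert tab["incremental_cost"].iloc[0] == pytest.approx(
            base.incremental_cost)

    def test_undiscounted_events_at_day_zero_invariant(self):
        # everything accrues in the first interval: discounting moves all
        # rows by the same factor, so the ICER is rate-invariant
        coh, mats = _dominance_fixture()
        coh["followup_days"] = 25.0
        coh["secondline_end_day"] = 10.0
        coh["true_death_day"] = 25.0
        tab = discount_sensitivity(coh, mats, rates=(0.0, 0.03),
                                   **ENGINE_OPTS)
        assert tab["icer_per_ly"].iloc[0] == pytest.approx(
            tab["icer_per_ly"].iloc[1], rel=1e-9)
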