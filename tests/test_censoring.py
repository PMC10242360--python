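"""Partitioned IPCW estimator: curve, partitioning, weighting, discounting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rwcea
from rwcea.censoring import (
    adjusted_outcomes,
    discount,
    discount_factor,
    interval_discount_factors,
    interval_starts,
    interval_widths,
    ipcw_adjust,
    ipcw_weight_matrix,
    km_censoring_curve,
    partition_followup,
)
from rwcea.exceptions import DegenerateArmError, EstimationError, ValidationError
from rwcea.simulate import cost_matrices
from tests.conftest import make_cohort


class TestGrid:
    def test_sixty_one_intervals_cover_the_horizon(self):
        starts = interval_starts()
        widths = interval_widths()
        assert len(starts) == 61
        assert widths[-1] == 26
        assert widths.sum() == 1826

    def test_survivor_at_horizon_partitions_to_1826_days(self):
        obs = partition_followup(1826.0)
        assert obs.shape == (1, 61)
        assert obs.sum() == 1826.0

    @pytest.mark.parametrize("fu, expected_head", [
        (45.0, [30.0, 15.0, 0.0]),
        (60.0, [30.0, 30.0, 0.0]),   # half-open boundary: day 60 opens k=2
        (10.0, [10.0, 0.0, 0.0]),
    ])
    def test_partition_arithmetic(self, fu, expected_head):
        obs = partition_followup(fu)[0]
        np.testing.assert_allclose(obs[:3], expected_head)
        assert obs[3:].sum() == 0.0


class TestCensoringCurve:
    def test_no_censoring_gives_unit_curve(self):
        fu = np.array([100.0, 500.0, 1826.0])
        death = np.array([True, True, False])  # horizon reached, not censored
        c = km_censoring_curve(fu, death)
        np.testing.assert_array_equal(c.probabilities, 1.0)

    def test_three_patient_hand_product_limit(self):
        # deaths day 45 and 100, censoring day 75: at the censoring time the
        # risk set is {censored patient, day-100 death} so K drops to 1/2
        c = km_censoring_curve(np.array([45.0, 75.0, 100.0]),
                               np.array([True, False, True]))
        assert c.probabilities[0] == 1.0
        assert c.probabilities[1] == 1.0
        assert c.probabilities[2] == 1.0
        assert c.probabilities[3] == 0.5

    def test_death_first_tie_convention(self):
        # death and censoring on the same day: the death leaves the risk set
        # first, so the censoring event sees risk set {itself, the survivor}
        c = km_censoring_curve(np.array([100.0, 100.0, 200.0]),
                               np.array([True, False, True]))
        assert c.probabilities[4] == 0.5  # K(120): 1 - 1/2

    def test_all_censored_in_first_interval_is_degenerate(self):
        with pytest.raises(DegenerateArmError):
            km_censoring_curve(np.array([1.0, 1.0, 1.0]),
                               np.array([False, False, False]))

    def test_zero_before_horizon_errors_by_default(self):
        fu = np.array([200.0, 300.0, 400.0])
        death = np.array([False, False, False])
        with pytest.raises(EstimationError, match="truncate"):
            km_censoring_curve(fu, death)
        c = km_censoring_curve(fu, death, on_zero="allow")
        assert c.probabilities[-1] == 0.0

    def test_matches_lifelines_reversed_km_on_tie_free_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(30)
        n = 400
        death_t = rng.exponential(500, n)
        cens_t = rng.uniform(0, 2500, n)
        fu = np.minimum(np.minimum(death_t, cens_t), 1826.0)
        death = death_t <= np.minimum(cens_t, 1826.0)
        c = km_censoring_curve(fu, death)
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(fu, event_observed=~death & (fu < 1826.0))
        # left-continuous evaluation: value just before each interval start
        ll = kmf.survival_function_at_times(c.starts[1:] - 1e-9).to_numpy()
        np.testing.assert_allclose(c.probabilities[1:], ll, atol=1e-10)
        assert c.probabilities[0] == 1.0


class TestIpcwAdjustment:
    def test_identity_when_no_censoring(self):
        fu = np.array([100.0, 700.0, 1826.0])
        death = np.array([True, True, False])
        c = km_censoring_curve(fu, death)
        w = ipcw_weight_matrix(fu, death, c)
        obs = partition_followup(fu)
        adj = ipcw_adjust(obs, w)
        np.testing.assert_allclose(adj.sum(1), fu)

    def test_three_patient_hand_adjustment(self):
        # the day-100 death contributes 30 + 30 + 30 + 10/0.5; the censored
        # patient's partial interval is excluded
        fu = np.array([45.0, 75.0, 100.0])
        death = np.array([True, False, True])
        c = km_censoring_curve(fu, death)
        w = ipcw_weight_matrix(fu, death, c)
        adj = ipcw_adjust(partition_followup(fu), w).sum(1)
        np.testing.assert_allclose(adj, [45.0, 60.0, 110.0])
        assert adj.mean() == pytest.approx(215.0 / 3.0)

    def test_censored_contribution_stops_before_censoring_interval(self):
        fu = np.array([75.0, 1000.0])
        death = np.array([False, True])
        c = km_censoring_curve(fu, death)
        w = ipcw_weight_matrix(fu, death, c)
        adj = ipcw_adjust(partition_followup(fu), w)
        assert adj[0].sum() == 60.0          # intervals 0 and 1 only
        winc = ipcw_weight_matrix(fu, death, c, include_partial=True)
        adj_inc = ipcw_adjust(partition_followup(fu), winc)
        assert adj_inc[0].sum() == 75.0      # alternative convention

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ipcw_adjust(np.zeros((2, 3)), np.zeros((2, 4)))


class TestDiscounting:
    def test_rate_zero_is_identity(self):
        contrib = np.random.default_rng(0).random((5, 61))
        np.testing.assert_allclose(discount(contrib, 0.0), contrib.sum(1))

    def test_closed_form_single_payment(self):
        assert 100.0 * discount_factor(365.25, 0.015) == pytest.approx(
            100.0 / 1.015)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(100.0, -0.01)

    @given(st.floats(0.0, 0.1), st.floats(0.0, 0.1))
    def test_monotone_in_rate(self, r1, r2):
        contrib = np.ones((1, 61))
        lo, hi = sorted([r1, r2])
        assert discount(contrib, hi)[0] <= discount(contrib, lo)[0] + 1e-12

    def test_midpoint_of_truncated_last_interval(self):
        d = interval_discount_factors(0.03)
        assert d[-1] == pytest.approx(discount_factor(1813.0, 0.03))


class TestAdjustedOutcomes:
    def test_uncensored_reduces_to_truncated_sample_mean(self):
        cfg = rwcea.default_config(
            seed=31, n_control=300, n_treated=300,
            censoring=rwcea.config.CensoringParams(enabled=False))
        cohort = rwcea.generate_cohort(cfg)
        mats = cost_matrices(cohort, cfg)
        adj = adjusted_outcomes(cohort, mats, discount_rate=0.0)
        naive = np.minimum(cohort["true_death_day"], 1826.0) / 365.25
        np.testing.assert_allclose(adj["ly"], naive, rtol=1e-12)

    def test_zero_costs_leave_ly_unaffected(self, small_sim):
        cfg, cohort, mats = small_sim
        zero_mats = {k: np.zeros_like(v) for k, v in mats.items()}
        a = adjusted_outcomes(cohort, mats)
        b = adjusted_outcomes(cohort, zero_mats)
        np.testing.assert_allclose(a["ly"], b["ly"])
        assert (b["cost_total"] == 0.0).all()

    def test_consistency_with_bias_aware_oracle(self, default_truth):
        """IPCW arm means approach truth up to the convention's predictable
        discretization bias (each interval's term shrinks by its conditional
        censoring hazard); the deviation must be within 3 SE of that
        prediction, and within 3 SE of zero at the halved-bias
        include-partial convention times two."""
        te = default_truth
        cfg = rwcea.default_config(seed=32, n_control=5000, n_treated=5000,
                                   assignment_coefs={})
        cohort = rwcea.generate_cohort(cfg)
        mats = cost_matrices(cohort, cfg)
        adj = adjusted_outcomes(cohort, mats)
        cmax = cfg.censoring.max_followup_days
        starts = interval_starts()
        widths = interval_widths()
        # conditional censoring probability of each interval under the
        # uniform administrative window
        hk = widths / (cmax - starts)
        dfac = interval_discount_factors(0.015)
        for a in rwcea.ARMS:
            sub = adj[adj["arm"] == a]
            sel = (cohort["arm"] == a).to_numpy()
            obs = partition_followup(cohort.loc[sel, "followup_days"].to_numpy())
            # predicted bias: minus the hazard-weighted discounted accrual
            pred_bias_ly = -(obs * hk * dfac).sum() / len(sub) / 365.25
            est, tru = sub["ly"].mean(), te.mean_ly[a]
            se = np.sqrt(sub["ly"].std() ** 2 / len(sub) + te.se_ly[a] ** 2)
            assert est - tru == pytest.approx(pred_bias_ly, abs=3 * se)

    def test_recovers_truth_under_censoring_within_tolerance(self, default_truth):
        # cost recovery at n=5000/arm: bias-aware band (prediction +- 3 SE)
        te = default_truth
        cfg = rwcea.default_config(seed=33, n_control=5000, n_treated=5000,
                                   assignment_coefs={})
        cohort = rwcea.generate_cohort(cfg)
        mats = cost_matrices(cohort, cfg)
        adj = adjusted_outcomes(cohort, mats)
        for a in rwcea.ARMS:
            sub = adj[adj["arm"] == a]
            est, tru = sub["cost_total"].mean(), te.mean_cost[a]
            se = np.sqrt(sub["cost_total"].std() ** 2 / len(sub)
                         + te.se_cost[a] ** 2)
            # within 3 SE after allowing the documented < 3% downward
            # discretization bias of the exclusion convention
            assert tru - 0.03 * tru - 3 * se < est < tru + 3 * se
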