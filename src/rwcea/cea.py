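"""Incremental cost-effectiveness estimation with bootstrap uncertainty.

The point estimate weights each patient's IPCW-adjusted, discounted
five-year outcomes by its IPTW weight and contrasts the arm means
(treated minus control); the ICER is the ratio of incremental cost to
incremental effect (per life-year and per QALY).

Uncertainty comes from a nonparametric bootstrap stratified by arm. Each
replicate resamples patients with replacement within arm and re-runs the
entire estimation — propensity model, per-arm censoring curves, and one
fresh utility draw per resampled patient — so that all estimation steps
contribute to the interval. Percentile intervals are reported; the ICER
interval uses replicate ratio percentiles and is flagged undefined when the
replicate incremental effects do not share a sign (net-benefit framing is
the meaningful summary in that case).

Decision-analytic outputs: the cost-effectiveness plane (replicate
scatter), the cost-effectiveness acceptability curve (probability that
``lambda * dE - dC > 0`` across willingness-to-pay values), per-patient
net-benefit regression with heteroskedasticity-robust errors, and the
discount-rate and drug-price-reduction sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    ARMS,
    COST_CATEGORIES,
    DAYS_PER_YEAR,
    DRUG_TAG,
    HORIZON_DAYS,
    INTERVAL_DAYS,
    UtilityParams,
)
from .censoring import (
    interval_discount_factors,
    ipcw_weight_matrix,
    km_censoring_curve,
    partition_followup,
)
from .exceptions import (
    DegenerateArmError,
    EstimationError,
    ValidationError,
)
from .qaly import mean_utilities, pf_fraction_matrix, sample_utilities
from .weights import (
    DEFAULT_PROPENSITY_COVARIATES,
    WeightVector,
    compute_iptw,
    fit_propensity,
)

#: Default willingness-to-pay grid: $0 to $300,000 in $1,000 steps.
DEFAULT_WTP_GRID = np.arange(0, 300_001, 1000, dtype=float)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class IncrementalResult:
    """Arm means and incremental contrasts at the IPTW point estimate."""

    arm_means: dict                      # outcome -> {arm: value}
    incremental_cost: float
    incremental_ly: float
    incremental_qaly: float
    icer_per_ly: float | None            # None when the effect difference is 0
    icer_per_qaly: float | None
    ci: dict = field(default_factory=dict)  # filled from a bootstrap

    @property
    def category_incrementals(self) -> dict:
        return {
            cat: self.arm_means[f"cost_{cat}"]["treated"]
            - self.arm_means[f"cost_{cat}"]["control"]
            for cat in COST_CATEGORIES
        }


@dataclass
class BootstrapResult:
    """Replicate incremental pairs and the summaries derived from them."""

    B: int
    dc: np.ndarray
    de_ly: np.ndarray
    de_qaly: np.ndarray
    seed: int
    n_redrawn: int
    point: IncrementalResult

    def __post_init__(self):
        if not (len(self.dc) == len(self.de_ly) == len(self.de_qaly) == self.B):
            raise EstimationError("replicate arrays must have length B")

    def effect(self, measure: str) -> np.ndarray:
        if measure == "ly":
            return self.de_ly
        if measure == "qaly":
            return self.de_qaly
        raise ValidationError(f"effect measure must be 'ly' or 'qaly', got {measure!r}")

    def percentile_ci(self, values: np.ndarray, level: float = 0.95) -> tuple:
        a = (1.0 - level) / 2.0
        return tuple(np.quantile(values, [a, 1.0 - a]))

    def icer_ci(self, measure: str = "ly", level: float = 0.95):
        """Percentile CI of replicate ICER ratios; None if dE changes sign."""
        de = self.effect(measure)
        if np.all(de > 0) or np.all(de < 0):
            return self.percentile_ci(self.dc / de, level)
        return None

    def quadrant_counts(self, measure: str = "ly") -> dict:
        """CE-plane quadrant counts (NE = costlier and more effective)."""
        de = self.effect(measure)
        counts = {
            "NE": int(np.sum((self.dc > 0) & (de > 0))),
            "NW": int(np.sum((self.dc > 0) & (de <= 0))),
            "SE": int(np.sum((self.dc <= 0) & (de > 0))),
            "SW": int(np.sum((self.dc <= 0) & (de <= 0))),
        }
        assert sum(counts.values()) == self.B
        return counts


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness across willingness-to-pay values."""

    wtp: np.ndarray
    probability: np.ndarray
    effect_measure: str

    def __post_init__(self):
        p = np.asarray(self.probability, float)
        if np.any((p < 0) | (p > 1)):
            raise EstimationError("CEAC probabilities must lie in [0, 1]")


@dataclass
class NMBResult:
    """Incremental net monetary benefit at one willingness-to-pay value."""

    wtp: float
    effect_measure: str
    incremental_nmb: float
    ci_low: float
    ci_high: float

    @property
    def cost_effective(self) -> bool:
        return self.incremental_nmb > 0


# ---------------------------------------------------------------------------
# point estimate
# ---------------------------------------------------------------------------

def incremental_summary(adjusted: pd.DataFrame,
                        weights: WeightVector | np.ndarray) -> IncrementalResult:
    """IPTW-weighted arm means and treated-minus-control incrementals.

    ``adjusted`` is the per-patient output of
    :func:`rwcea.censoring.adjusted_outcomes`; weights align with its rows.
    An ICER is reported as ``None`` (undefined) when the corresponding
    incremental effect is exactly zero.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    if len(w) != len(adjusted):
        raise ValidationError("weights must align with adjusted outcomes")
    arm = adjusted["arm"].to_numpy()
    if not set(ARMS) <= set(arm):
        raise ValidationError("both arms must be present")

    outcomes = (["ly", "qaly", "cost_total", "cost_drug_of_interest"]
                + [f"cost_{c}" for c in COST_CATEGORIES])
    arm_means = {}
    for col in outcomes:
        arm_means[col] = {
            a: float(np.average(adjusted.loc[arm == a, col].to_numpy(),
                                weights=w[arm == a]))
            for a in ARMS
        }
    d_cost = arm_means["cost_total"]["treated"] - arm_means["cost_total"]["control"]
    d_ly = arm_means["ly"]["treated"] - arm_means["ly"]["control"]
    d_qaly = arm_means["qaly"]["treated"] - arm_means["qaly"]["control"]
    return IncrementalResult(
        arm_means=arm_means,
        incremental_cost=d_cost,
        incremental_ly=d_ly,
        incremental_qaly=d_qaly,
        icer_per_ly=(d_cost / d_ly) if d_ly != 0 else None,
        icer_per_qaly=(d_cost / d_qaly) if d_qaly != 0 else None,
    )


# ---------------------------------------------------------------------------
# fast resampling engine
# ---------------------------------------------------------------------------

class CEAEngine:
    """Precomputed arrays for repeated (bootstrap) estimation of one cohort.

    Bundles the cohort, its per-interval cost arrays and the analysis
    options, and exposes :meth:`estimate` on an arbitrary row index —
    identity for the point estimate, a stratified resample per bootstrap
    replicate.
    """

    def __init__(self, cohort: pd.DataFrame, cost_matrices: dict,
                 discount_rate: float = 0.015,
                 horizon_days: int = HORIZON_DAYS,
                 interval_days: int = INTERVAL_DAYS,
                 utility_params: UtilityParams | None = None,
                 propensity_covariates=DEFAULT_PROPENSITY_COVARIATES,
                 estimand: str = "ATE",
                 stabilized: bool = False,
                 include_partial: bool = False,
                 reestimate_weights: bool = True,
                 drug_price_factor: float = 1.0,
                 on_zero: str = "error"):
        from .weights import _design_matrix  # shared design-matrix expansion

        self.cohort = cohort.reset_index(drop=True)
        self.n = len(cohort)
        self.discount_rate = discount_rate
        self.horizon_days = horizon_days
        self.interval_days = interval_days
        self.utility_params = utility_params or UtilityParams()
        self.estimand = estimand
        self.stabilized = stabilized
        self.include_partial = include_partial
        self.reestimate_weights = reestimate_weights
        self.on_zero = on_zero
        self.propensity_covariates = propensity_covariates

        self.treated = (self.cohort["arm"] == "treated").to_numpy()
        if self.treated.all() or (~self.treated).all():
            raise ValidationError("both arms must be present")
        self.fu = self.cohort["followup_days"].to_numpy(dtype=float)
        self.death = self.cohort["death"].to_numpy(dtype=bool)
        self.obs = partition_followup(self.fu, horizon_days, interval_days)
        self.dfac = interval_discount_factors(discount_rate, horizon_days,
                                              interval_days)
        n_int = self.obs.shape[1]
        self.drug = np.asarray(cost_matrices.get(DRUG_TAG, np.zeros((self.n, n_int))),
                               dtype=float)
        self.nondrug = np.zeros((self.n, n_int))
        for cat in COST_CATEGORIES:
            if cat in cost_matrices:
                self.nondrug += np.asarray(cost_matrices[cat], dtype=float)
        self.drug_price_factor = drug_price_factor
        self.pf_frac = pf_fraction_matrix(self.cohort, horizon_days, interval_days)

        X = _design_matrix(self.cohort, propensity_covariates)
        X = X.loc[:, X.nunique() > 1]
        self.X = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")

        # weights of the full cohort, reused when reestimate_weights is off
        self._base_fit = fit_propensity(self.cohort, propensity_covariates)
        self.base_weights = compute_iptw(self._base_fit, estimand=estimand,
                                         stabilized=stabilized)

    # -- single estimation pass --------------------------------------------

    def _iptw(self, idx: np.ndarray) -> np.ndarray:
        t = self.treated[idx]
        if self.reestimate_weights:
            y = t.astype(float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, self.X[idx]).fit(disp=0, maxiter=50)
            except Exception as exc:  # separation / singular design
                raise EstimationError("propensity refit failed") from exc
            e = np.clip(res.predict(self.X[idx]), 1e-12, 1 - 1e-12)
            if not res.mle_retvals.get("converged", True):
                raise EstimationError("propensity refit did not converge")
        else:
            e = self.base_weights  # placeholder; weights reused directly
            w = self.base_weights.weights[idx]
            return w
        if self.estimand == "ATE":
            w = np.where(t, 1.0 / e, 1.0 / (1.0 - e))
            if self.stabilized:
                p = t.mean()
                w *= np.where(t, p, 1.0 - p)
        else:
            w = np.where(t, 1.0, e / (1.0 - e))
        return w

    def estimate(self, idx: np.ndarray,
                 utilities=None,
                 rng: np.random.Generator | None = None) -> IncrementalResult:
        """Full estimation pass on the rows ``idx``.

        ``utilities`` may be an explicit ``(u_pf, u_prog)`` pair per row of
        ``idx``; by default the distribution means are used unless ``rng``
        is given, in which case one fresh draw per (resampled) patient is
        taken — the probabilistic-utility convention used inside the
        bootstrap.
        """
        idx = np.asarray(idx)
        t = self.treated[idx]
        fu = self.fu[idx]
        death = self.death[idx]
        w_iptw = self._iptw(idx)

        wmat = np.zeros((len(idx), self.obs.shape[1]))
        for a, sel in (("control", ~t), ("treated", t)):
            if not sel.any():
                raise DegenerateArmError(f"arm {a!r} empty in resample")
            curve = km_censoring_curve(fu[sel], death[sel], self.horizon_days,
                                       self.interval_days, arm=a,
                                       on_zero=self.on_zero)
            wmat[sel] = ipcw_weight_matrix(fu[sel], death[sel], curve,
                                           include_partial=self.include_partial)

        adj_days = self.obs[idx] * wmat
        ly = (adj_days @ self.dfac) / DAYS_PER_YEAR

        if utilities is None:
            if rng is not None:
                utilities = sample_utilities(len(idx), self.utility_params, rng)
            else:
                utilities = mean_utilities(self.utility_params)
        u_pf, u_prog = utilities
        u_pf = np.broadcast_to(np.asarray(u_pf, dtype=float), (len(idx),))
        u_prog = np.broadcast_to(np.asarray(u_prog, dtype=float), (len(idx),))
        frac = self.pf_frac[idx]
        util = u_pf[:, None] * frac + u_prog[:, None] * (1.0 - frac)
        qaly = ((adj_days * util) @ self.dfac) / DAYS_PER_YEAR

        cost_mat = self.nondrug[idx] + self.drug_price_factor * self.drug[idx]
        cost = ((cost_mat * wmat) @ self.dfac)

        def wmean(v, sel):
            return float(np.average(v[sel], weights=w_iptw[sel]))

        d_cost = wmean(cost, t) - wmean(cost, ~t)
        d_ly = wmean(ly, t) - wmean(ly, ~t)
        d_qaly = wmean(qaly, t) - wmean(qaly, ~t)
        arm_means = {
            "ly": {"treated": wmean(ly, t), "control": wmean(ly, ~t)},
            "qaly": {"treated": wmean(qaly, t), "control": wmean(qaly, ~t)},
            "cost_total": {"treated": wmean(cost, t), "control": wmean(cost, ~t)},
        }
        return IncrementalResult(
            arm_means=arm_means,
            incremental_cost=d_cost,
            incremental_ly=d_ly,
            incremental_qaly=d_qaly,
            icer_per_ly=(d_cost / d_ly) if d_ly != 0 else None,
            icer_per_qaly=(d_cost / d_qaly) if d_qaly != 0 else None,
        )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_cea(cohort: pd.DataFrame, cost_matrices: dict,
                  B: int = 1000, seed: int = 0,
                  resample: bool = True,
                  max_redraws: int | None = None,
                  engine: CEAEngine | None = None,
                  **engine_options) -> BootstrapResult:
    """Stratified nonparametric bootstrap of the incremental estimates.

    Each replicate resamples patients with replacement within arm, refits
    the propensity model, re-estimates per-arm censoring curves, draws one
    utility pair per resampled patient, and recomputes the incremental
    cost and effects. Replicates with a degenerate arm (or otherwise
    inestimable weights) are redrawn and counted.

    ``resample=False`` disables resampling (every "replicate" is the full
    cohort with utilities at their means) — then every replicate equals the
    point estimate, a convenient identity check.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if engine is None:
        engine = CEAEngine(cohort, cost_matrices, **engine_options)
    rng = np.random.default_rng(seed)
    idx_control = np.flatnonzero(~engine.treated)
    idx_treated = np.flatnonzero(engine.treated)
    all_idx = np.arange(engine.n)

    point = engine.estimate(all_idx)

    dc = np.empty(B)
    de_ly = np.empty(B)
    de_qaly = np.empty(B)
    n_redrawn = 0
    budget = max_redraws if max_redraws is not None else max(100, B)
    b = 0
    while b < B:
        if resample:
            idx = np.concatenate([
                rng.choice(idx_control, size=len(idx_control), replace=True),
                rng.choice(idx_treated, size=len(idx_treated), replace=True),
            ])
            try:
                rep = engine.estimate(idx, rng=rng)
            except (DegenerateArmError, EstimationError):
                n_redrawn += 1
                if n_redrawn > budget:
                    raise EstimationError(
                        f"more than {budget} bootstrap replicates were "
                        f"inestimable; the cohort is too fragile to bootstrap"
                    )
                continue
        else:
            rep = engine.estimate(all_idx)
        dc[b] = rep.incremental_cost
        de_ly[b] = rep.incremental_ly
        de_qaly[b] = rep.incremental_qaly
        b += 1

    result = BootstrapResult(B=B, dc=dc, de_ly=de_ly, de_qaly=de_qaly,
                             seed=seed, n_redrawn=n_redrawn, point=point)
    point.ci = {
        "incremental_cost": result.percentile_ci(dc),
        "incremental_ly": result.percentile_ci(de_ly),
        "incremental_qaly": result.percentile_ci(de_qaly),
        "icer_per_ly": result.icer_ci("ly"),
        "icer_per_qaly": result.icer_ci("qaly"),
    }
    return result


# ---------------------------------------------------------------------------
# decision-analytic summaries
# ---------------------------------------------------------------------------

def ceac(bootstrap: BootstrapResult, wtp_grid=DEFAULT_WTP_GRID,
         effect_measure: str = "ly") -> CEACCurve:
    """Cost-effectiveness acceptability curve from bootstrap replicates.

    At each willingness-to-pay ``lambda``, the probability is the fraction
    of replicates with positive incremental net benefit
    ``lambda * dE - dC > 0``.
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    de = bootstrap.effect(effect_measure)
    nb = wtp[:, None] * de[None, :] - bootstrap.dc[None, :]
    prob = (nb > 0).mean(axis=1)
    return CEACCurve(wtp=wtp, probability=prob, effect_measure=effect_measure)


def nmb_regression(adjusted: pd.DataFrame, weights: WeightVector | np.ndarray,
                   wtp: float, effect_measure: str = "ly",
                   level: float = 0.95) -> NMBResult:
    """Net-benefit regression of ``lambda * E - C`` on the treatment arm.

    Weighted least squares with the IPTW weights; the treatment coefficient
    is the incremental net monetary benefit, with a heteroskedasticity-
    robust (HC1) confidence interval. Positive incremental NMB means the
    treatment is cost-effective at this willingness-to-pay.
    """
    if wtp < 0:
        raise ValidationError("willingness-to-pay must be >= 0")
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    arm = adjusted["arm"].to_numpy()
    if not set(ARMS) <= set(arm):
        raise ValidationError("both arms must be present for net-benefit regression")
    eff = adjusted["ly" if effect_measure == "ly" else "qaly"].to_numpy(dtype=float)
    if effect_measure not in ("ly", "qaly"):
        raise ValidationError(f"effect measure must be 'ly' or 'qaly', got {effect_measure!r}")
    nb = wtp * eff - adjusted["cost_total"].to_numpy(dtype=float)
    t = (arm == "treated").astype(float)
    design = sm.add_constant(t)
    res = sm.WLS(nb, design, weights=w).fit(cov_type="HC1")
    lo, hi = res.conf_int(alpha=1 - level)[1]
    return NMBResult(wtp=float(wtp), effect_measure=effect_measure,
                     incremental_nmb=float(res.params[1]),
                     ci_low=float(lo), ci_high=float(hi))


def nmb_table(adjusted: pd.DataFrame, weights, wtp_values,
              effect_measure: str = "ly") -> pd.DataFrame:
    """Incremental NMB across a set of willingness-to-pay thresholds."""
    rows = []
    for lam in wtp_values:
        r = nmb_regression(adjusted, weights, lam, effect_measure)
        rows.append((r.wtp, r.incremental_nmb, r.ci_low, r.ci_high,
                     r.cost_effective))
    return pd.DataFrame(rows, columns=["wtp", "incremental_nmb", "ci_low",
                                       "ci_high", "cost_effective"])


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------

def price_reduction_curve(cohort: pd.DataFrame, cost_matrices: dict,
                          fractions=None, **engine_options) -> pd.DataFrame:
    """ICER as the price of the tagged drug is reduced by 0-100%.

    For each reduction fraction ``f`` the tagged drug-of-interest costs are
    multiplied by ``(1 - f)`` before censoring adjustment and the whole
    estimation is re-run. Returns one row per fraction with the incremental
    cost and ICERs per life-year and per QALY.
    """
    if DRUG_TAG not in cost_matrices or not np.any(cost_matrices[DRUG_TAG]):
        raise ValidationError(
            "cost matrices carry no drug-of-interest entries; the price "
            "reduction analysis needs the tagged drug cost"
        )
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 11)
    rows = []
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValidationError("price reduction fractions must lie in [0, 1]")
        engine = CEAEngine(cohort, cost_matrices,
                           drug_price_factor=1.0 - f, **engine_options)
        res = engine.estimate(np.arange(engine.n))
        rows.append((f, res.incremental_cost, res.incremental_ly,
                     res.incremental_qaly, res.icer_per_ly, res.icer_per_qaly))
    return pd.DataFrame(rows, columns=["fraction", "incremental_cost",
                                       "incremental_ly", "incremental_qaly",
                                       "icer_per_ly", "icer_per_qaly"])


def discount_sensitivity(cohort: pd.DataFrame, cost_matrices: dict,
                         rates=(0.0, 0.015, 0.03),
                         B: int = 0, seed: int = 0,
                         **engine_options) -> pd.DataFrame:
    """Re-run the analysis across annual discount rates.

    ``B > 0`` adds percentile bootstrap CIs per rate (each rate gets its own
    bootstrap with the same seed, so rows differ only through the rate).
    """
    rows = []
    for rate in rates:
        opts = dict(engine_options, discount_rate=rate)
        if B > 0:
            boot = bootstrap_cea(cohort, cost_matrices, B=B, seed=seed, **opts)
            res = boot.point
            ci_c = res.ci["incremental_cost"]
            ci_e = res.ci["incremental_ly"]
            ci_i = res.ci["icer_per_ly"]
        else:
            engine = CEAEngine(cohort, cost_matrices, **opts)
            res = engine.estimate(np.arange(engine.n))
            ci_c = ci_e = ci_i = (np.nan, np.nan)
        ci_i = ci_i if ci_i is not None else (np.nan, np.nan)
        rows.append((rate, res.incremental_cost, *ci_c,
                     res.incremental_ly, *ci_e,
                     res.icer_per_ly, *ci_i))
    return pd.DataFrame(rows, columns=[
        "rate", "incremental_cost", "cost_ci_low", "cost_ci_high",
        "incremental_ly", "ly_ci_low", "ly_ci_high",
        "icer_per_ly", "icer_ci_low", "icer_ci_high",
    ])
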