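"""Synthetic two-arm cohort and cost-ledger generation with known truth.

The generator produces patient-level data with the statistical structure a
real-world cost-effectiveness analysis of a newly funded second-line cancer
therapy must cope with:

* confounded treatment assignment — a logistic model on baseline covariates
  decides who receives the treatment of interest, so the arms differ in
  prognosis before any treatment effect;
* mixture-cure survival — most patients die within 1-2 years (Weibull, with
  covariate frailty shared across arms), while a small long-term survivor
  fraction (<= 15%) keeps each arm's survival curve flat near the horizon;
* a cost ledger by resource category on the 30-day grid, with the treated
  arm's drug acquisition cost charged per dose in the first weeks (front
  loaded) and a terminal-phase uplift on the last six months of life;
* administrative censoring — a uniform accrual window mapped to a
  per-patient maximum follow-up.

Because the process is fully parameterized, :func:`true_estimands` can
compute the censoring-free Monte-Carlo ground truth (discounted mean cost,
life-years, QALYs per arm under counterfactual assignment of everyone to
each arm) that estimator-recovery tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ARMS, COST_CATEGORIES, DRUG_TAG, SimConfig
from .censoring import interval_starts, interval_widths
from .exceptions import ConfigurationError, ValidationError


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _draw_covariates(rng: np.random.Generator, n: int, cfg: SimConfig) -> pd.DataFrame:
    cp = cfg.covariates
    age = np.clip(rng.normal(cp.age_mean, cp.age_sd, n), cp.age_min, cp.age_max)
    male = rng.random(n) < cp.p_male
    income = rng.choice(np.arange(1, 6), size=n, p=np.asarray(cp.income_probs))
    urban = rng.random(n) < cp.p_urban
    shape = (cp.morbidity_mean / cp.morbidity_sd) ** 2
    morbidity = rng.gamma(shape, cp.morbidity_mean / shape, n)
    adg = np.clip(np.round(rng.normal(cp.adg_mean, cp.adg_sd, n)), 0, None)
    charlson = rng.random(n) < cp.p_charlson_1plus
    prior_rad = rng.random(n) < cp.p_prior_radiation
    prior_res = rng.random(n) < cp.p_prior_resection
    fl_classes = list(cp.firstline_probs)
    firstline = rng.choice(fl_classes, size=n, p=[cp.firstline_probs[c] for c in fl_classes])
    months_dx = np.exp(rng.normal(cp.dx_months_log_mu, cp.dx_months_log_sd, n))
    return pd.DataFrame({
        "age": age,
        "male": male.astype(int),
        "income_quintile": income,
        "urban": urban.astype(int),
        "morbidity_score": morbidity,
        "adg_count": adg,
        "charlson_1plus": charlson.astype(int),
        "prior_radiation": prior_rad.astype(int),
        "prior_resection": prior_res.astype(int),
        "firstline_class": firstline,
        "months_dx_to_2l": months_dx,
    })


def _standardized_features(cov: pd.DataFrame, cfg: SimConfig) -> dict:
    """Centered/standardized covariate features keyed for coefficient dicts.

    Standardization uses the *configured* moments so that the assignment and
    frailty linear predictors are exact functions of the config, not of the
    realized sample.
    """
    cp = cfg.covariates
    return {
        "age": (cov["age"] - cp.age_mean) / cp.age_sd,
        "morbidity": (cov["morbidity_score"] - cp.morbidity_mean) / cp.morbidity_sd,
        "adg": (cov["adg_count"] - cp.adg_mean) / cp.adg_sd,
        "months_dx": (np.log(cov["months_dx_to_2l"]) - cp.dx_months_log_mu)
        / cp.dx_months_log_sd,
        "male": cov["male"] - cp.p_male,
        "urban": cov["urban"] - cp.p_urban,
        "charlson": cov["charlson_1plus"] - cp.p_charlson_1plus,
        "prior_radiation": cov["prior_radiation"] - cp.p_prior_radiation,
        "prior_resection": cov["prior_resection"] - cp.p_prior_resection,
        "firstline_braf": (cov["firstline_class"] == "braf_mek").astype(float)
        - cp.firstline_probs.get("braf_mek", 0.0),
        "firstline_other": (cov["firstline_class"] == "other").astype(float)
        - cp.firstline_probs.get("other", 0.0),
    }


def _linear_predictor(features: dict, coefs: dict) -> np.ndarray:
    n = len(next(iter(features.values())))
    lin = np.zeros(n)
    for name, coef in coefs.items():
        if name not in features:
            raise ConfigurationError(f"unknown coefficient key: {name!r}")
        lin += coef * np.asarray(features[name], dtype=float)
    return lin


# ---------------------------------------------------------------------------
# event times
# ---------------------------------------------------------------------------

def _simulate_death_days(rng, cfg: SimConfig, arm: np.ndarray,
                         frailty_eta: np.ndarray) -> np.ndarray:
    """True death day per patient (inf for long-term survivors)."""
    n = len(arm)
    death = np.empty(n)
    u_cure = rng.random(n)
    for a in ARMS:
        sel = arm == a
        sp = cfg.survival[a]
        w_a = rng.weibull(sp.weibull_shape, int(sel.sum()))
        t = sp.weibull_scale_days * np.exp(-frailty_eta[sel]) * w_a
        cured = u_cure[sel] < sp.cure_fraction
        death[sel] = np.where(cured, np.inf, t)
    return death


def _simulate_progression(rng, cfg: SimConfig, arm: np.ndarray,
                          death_day: np.ndarray,
                          followup: np.ndarray) -> tuple:
    """Observed second-line end and third-line start days."""
    pp = cfg.progression
    n = len(arm)
    dur = np.empty(n)
    for a in ARMS:
        sel = arm == a
        m, s = pp.secondline_mean_days[a], pp.secondline_sd_days[a]
        shape = (m / s) ** 2
        dur[sel] = rng.gamma(shape, m / shape, int(sel.sum()))
    sl_end = np.minimum(np.minimum(dur, death_day), followup)

    delay_m, delay_s = pp.thirdline_delay_mean_days, pp.thirdline_delay_sd_days
    shape3 = (delay_m / delay_s) ** 2
    t3 = sl_end + rng.gamma(shape3, delay_m / shape3, n)
    has_t3 = (rng.random(n) < pp.p_thirdline) & (t3 < followup)
    t3 = np.where(has_t3, t3, np.nan)
    return sl_end, t3


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw a two-arm cohort of ``n_control + n_treated`` patients.

    Treatment is assigned by the configured logistic model (intercept fixed
    at ``logit(n_treated / n_total)`` on centered covariates, so with zero
    coefficients the expected treated fraction equals the configured one).
    Observed follow-up is ``min(death, administrative censoring, horizon)``.

    The returned frame includes the ground-truth column ``true_death_day``
    (inf for long-term survivors). It exists for simulator bookkeeping and
    estimator-recovery tests; the analysis pipeline never reads it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_treated

    cov = _draw_covariates(rng, n, config)
    feats = _standardized_features(cov, config)

    base_logit = np.log(config.n_treated / config.n_control)
    p_treat = 1.0 / (1.0 + np.exp(-(base_logit
                                    + _linear_predictor(feats, config.assignment_coefs))))
    arm = np.where(rng.random(n) < p_treat, "treated", "control")

    eta = _linear_predictor(feats, config.frailty_coefs)
    death_day = _simulate_death_days(rng, config, arm, eta)

    if config.censoring.enabled:
        cens = rng.uniform(config.censoring.min_followup_days,
                           config.censoring.max_followup_days, n)
    else:
        cens = np.full(n, np.inf)
    followup = np.minimum(np.minimum(death_day, cens), float(config.horizon_days))
    died = death_day <= np.minimum(cens, float(config.horizon_days))

    sl_end, t3 = _simulate_progression(rng, config, arm, death_day, followup)

    out = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "arm": arm,
    })
    out = pd.concat([out, cov], axis=1)
    out["followup_days"] = followup
    out["death"] = died.astype(int)
    out["secondline_end_day"] = sl_end
    out["thirdline_start_day"] = t3
    out["true_death_day"] = death_day
    return out


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def cost_matrices(cohort: pd.DataFrame, config: SimConfig,
                  rng: np.random.Generator | None = None,
                  noise: bool = True) -> dict:
    """Per-interval cost arrays (CAD) by category, aligned with cohort rows.

    Background care in each category accrues at the arm's base monthly rate
    per 30 observed days; intervals overlapping the last six months before
    (true) death are scaled by the terminal uplift. With ``noise=True``
    (default) the per-interval amounts are gamma-distributed around their
    expectation with coefficient of variation ``config.cost_cv``. Drug
    acquisition cost is charged exactly (no noise) on each scheduled dose
    day the patient is still on second-line treatment, under the key
    ``"drug_of_interest"``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    fu = cohort["followup_days"].to_numpy(dtype=float)
    death_day = cohort["true_death_day"].to_numpy(dtype=float)
    arm = cohort["arm"].to_numpy()
    sl_end = cohort["secondline_end_day"].to_numpy(dtype=float)
    n = len(cohort)

    starts = interval_starts(config.horizon_days, config.interval_days)
    widths = interval_widths(config.horizon_days, config.interval_days)
    obs = np.clip(fu[:, None] - starts[None, :], 0.0, widths[None, :])

    # observed days falling in the terminal window [death - w, death)
    term_lo = np.where(np.isfinite(death_day),
                       death_day - config.terminal_window_days, np.inf)
    upper = np.minimum(np.minimum(fu, death_day)[:, None], starts[None, :] + widths[None, :])
    lower = np.maximum(starts[None, :], term_lo[:, None])
    term_days = np.clip(upper - lower, 0.0, None)
    term_days = np.minimum(term_days, obs)
    effective_days = obs + (config.terminal_uplift - 1.0) * term_days

    cv2 = config.cost_cv ** 2
    mats = {}
    for cat in COST_CATEGORIES:
        mu = np.zeros_like(obs)
        for a in ARMS:
            sel = arm == a
            rate = config.costs[a].monthly_rates.get(cat, 0.0)
            mu[sel] = rate / 30.0 * effective_days[sel]
        if noise and cv2 > 0:
            amounts = np.where(mu > 0,
                               rng.gamma(1.0 / cv2, np.where(mu > 0, mu, 1.0) * cv2),
                               0.0)
        else:
            amounts = mu
        mats[cat] = amounts

    drug = np.zeros_like(obs)
    treated = arm == "treated"
    for d in config.drug.dose_days:
        k = int(d // config.interval_days)
        given = treated & (sl_end > d)
        drug[given, k] += config.drug.cost_per_dose
    mats[DRUG_TAG] = drug
    return mats


def generate_cost_ledger(cohort: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Long-format cost ledger: one row per patient-interval-category entry.

    Columns: ``patient_id, interval, category, amount, drug_of_interest``.
    Drug acquisition entries carry ``category == "systemic_therapy"`` with
    the ``drug_of_interest`` flag set. All entries lie within the patient's
    observed follow-up.
    """
    mats = cost_matrices(cohort, config, rng=rng)
    pid = cohort["patient_id"].to_numpy()
    frames = []
    for cat in COST_CATEGORIES:
        i, k = np.nonzero(mats[cat])
        frames.append(pd.DataFrame({
            "patient_id": pid[i],
            "interval": k,
            "category": cat,
            "amount": mats[cat][i, k],
            "drug_of_interest": False,
        }))
    i, k = np.nonzero(mats[DRUG_TAG])
    frames.append(pd.DataFrame({
        "patient_id": pid[i],
        "interval": k,
        "category": "systemic_therapy",
        "amount": mats[DRUG_TAG][i, k],
        "drug_of_interest": True,
    }))
    ledger = pd.concat(frames, ignore_index=True)
    return ledger.sort_values(["patient_id", "interval", "category"],
                              kind="stable").reset_index(drop=True)


def ledger_to_matrices(cohort: pd.DataFrame, ledger: pd.DataFrame,
                       horizon_days: int, interval_days: int) -> dict:
    """Pivot a long-format ledger into per-category cost arrays.

    Validates that every entry refers to a known patient and lies within
    that patient's observed follow-up.
    """
    n_int = len(interval_starts(horizon_days, interval_days))
    pid_index = {p: i for i, p in enumerate(cohort["patient_id"])}
    fu = cohort["followup_days"].to_numpy(dtype=float)

    unknown = set(ledger["patient_id"]) - set(pid_index)
    if unknown:
        raise ValidationError(f"ledger refers to unknown patients: {sorted(unknown)[:5]}")
    rows = ledger["patient_id"].map(pid_index).to_numpy()
    k = ledger["interval"].to_numpy(dtype=int)
    if np.any((k < 0) | (k >= n_int)):
        raise ValidationError("ledger interval index outside the horizon grid")
    entry_start = k * interval_days
    beyond = entry_start >= np.maximum(fu[rows], 1e-12)
    if np.any(beyond):
        bad = ledger.loc[beyond, "patient_id"].unique()[:5]
        raise ValidationError(
            f"ledger entries beyond observed follow-up for patients: {list(bad)}"
        )
    if np.any(ledger["amount"].to_numpy() < 0):
        raise ValidationError("ledger amounts must be nonnegative")

    mats = {cat: np.zeros((len(cohort), n_int)) for cat in COST_CATEGORIES}
    mats[DRUG_TAG] = np.zeros((len(cohort), n_int))
    amount = ledger["amount"].to_numpy(dtype=float)
    is_drug = ledger["drug_of_interest"].to_numpy(dtype=bool)
    cats = ledger["category"].to_numpy()
    for cat in COST_CATEGORIES:
        sel = (cats == cat) & ~is_drug
        np.add.at(mats[cat], (rows[sel], k[sel]), amount[sel])
    np.add.at(mats[DRUG_TAG], (rows[is_drug], k[is_drug]), amount[is_drug])
    unknown_cats = set(cats) - set(COST_CATEGORIES)
    if unknown_cats:
        raise ValidationError(f"unknown cost categories: {sorted(unknown_cats)}")
    return mats


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class TrueEstimands:
    """Monte-Carlo ground truth of the simulator's discounted estimands.

    Means are counterfactual: every simulated patient is assigned to the
    arm in question, with censoring disabled, so these are the
    population-average (ATE) quantities the IPTW + IPCW pipeline targets.
    """

    mean_cost: dict          # arm -> CAD
    mean_ly: dict            # arm -> years
    mean_qaly: dict          # arm -> years (utilities at their means)
    se_cost: dict
    se_ly: dict
    incremental_cost: float
    incremental_ly: float
    incremental_qaly: float
    icer_per_ly: float
    icer_per_qaly: float
    discount_rate: float
    n_mc: int


def true_estimands(config: SimConfig, n_mc: int = 100_000,
                   discount_rate: float = 0.015,
                   seed: int | None = None) -> TrueEstimands:
    """Censoring-free Monte-Carlo ground truth at the configured parameters.

    Simulates ``n_mc`` patients per arm (everyone counterfactually assigned
    to that arm, covariates drawn from the common population), accrues
    expected costs (noise-free) and survival on the 30-day grid, discounts
    at interval midpoints, and averages. Standard errors are patient-level
    SDs over ``sqrt(n_mc)``.
    """
    config.validate()
    if n_mc < 1000:
        raise ConfigurationError("n_mc must be >= 1000 for a usable ground truth")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 11]))

    from .censoring import adjusted_outcomes  # deferred to avoid cycle at import
    from .qaly import mean_utilities

    mean_cost, mean_ly, mean_qaly, se_cost, se_ly = {}, {}, {}, {}, {}
    for a in ARMS:
        cov = _draw_covariates(rng, n_mc, config)
        feats = _standardized_features(cov, config)
        eta = _linear_predictor(feats, config.frailty_coefs)
        arm = np.full(n_mc, a)
        death_day = _simulate_death_days(rng, config, arm, eta)
        followup = np.minimum(death_day, float(config.horizon_days))
        sl_end, t3 = _simulate_progression(rng, config, arm, death_day, followup)

        cohort = pd.DataFrame({
            "patient_id": np.arange(n_mc).astype(str),
            "arm": arm,
            "followup_days": followup,
            "death": (death_day <= config.horizon_days).astype(int),
            "secondline_end_day": sl_end,
            "thirdline_start_day": t3,
            "true_death_day": death_day,
        })
        mats = cost_matrices(cohort, config, rng=rng, noise=False)
        adj = adjusted_outcomes(cohort, mats, discount_rate=discount_rate,
                                horizon_days=config.horizon_days,
                                interval_days=config.interval_days,
                                utilities=mean_utilities(config.utilities))
        mean_cost[a] = float(adj["cost_total"].mean())
        mean_ly[a] = float(adj["ly"].mean())
        mean_qaly[a] = float(adj["qaly"].mean())
        se_cost[a] = float(adj["cost_total"].std(ddof=1) / np.sqrt(n_mc))
        se_ly[a] = float(adj["ly"].std(ddof=1) / np.sqrt(n_mc))

    d_cost = mean_cost["treated"] - mean_cost["control"]
    d_ly = mean_ly["treated"] - mean_ly["control"]
    d_qaly = mean_qaly["treated"] - mean_qaly["control"]
    return TrueEstimands(
        mean_cost=mean_cost, mean_ly=mean_ly, mean_qaly=mean_qaly,
        se_cost=se_cost, se_ly=se_ly,
        incremental_cost=d_cost, incremental_ly=d_ly, incremental_qaly=d_qaly,
        icer_per_ly=d_cost / d_ly if d_ly != 0 else float("nan"),
        icer_per_qaly=d_cost / d_qaly if d_qaly != 0 else float("nan"),
        discount_rate=discount_rate, n_mc=n_mc,
    )
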