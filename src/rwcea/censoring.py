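"""Partitioned IPCW estimation of censor-adjusted discounted costs and life-years.

Follow-up is divided into half-open 30-day intervals from the index date.
Within each treatment arm, the probability ``K(t)`` of remaining uncensored
at each interval start is estimated by a reversed Kaplan-Meier product-limit
(censoring is the event; death removes a patient from the risk set without
an event). Each patient's per-interval observed time and costs are divided
by ``K`` at the interval start, discounted at the interval midpoint, and
summed — the partitioned inverse-probability-of-censoring-weighted (IPCW)
estimator of the five-year mean.

Conventions (all exposed, none silent):

* ``K`` is evaluated left-continuously: censoring events strictly before an
  interval start reduce ``K`` at that start.
* When a death and a censoring fall on the same day, the death leaves the
  risk set first (it cannot be "at risk" of the censoring it precedes).
* A censored patient's partial interval is excluded by default: the weight
  ``1/K(start)`` is valid for patients observed through the interval, and
  mixing partial accrual into it would mix conventions. Set
  ``include_partial=True`` for the alternative convention.
* Discounting multiplies each interval's contribution by
  ``(1 + rate) ** (-t_mid / 365.25)`` with ``t_mid`` the interval midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    ARMS,
    COST_CATEGORIES,
    DAYS_PER_YEAR,
    HORIZON_DAYS,
    INTERVAL_DAYS,
)
from .exceptions import DegenerateArmError, EstimationError, ValidationError


# ---------------------------------------------------------------------------
# interval grid and discounting
# ---------------------------------------------------------------------------

def interval_starts(horizon_days: int = HORIZON_DAYS,
                    interval_days: int = INTERVAL_DAYS) -> np.ndarray:
    """Start days of the half-open intervals covering ``[0, horizon)``."""
    return np.arange(0, horizon_days, interval_days, dtype=float)


def interval_widths(horizon_days: int = HORIZON_DAYS,
                    interval_days: int = INTERVAL_DAYS) -> np.ndarray:
    """Interval widths in days; the last interval is truncated at the horizon."""
    starts = interval_starts(horizon_days, interval_days)
    return np.minimum(starts + interval_days, horizon_days) - starts


def discount_factor(t_days, annual_rate: float):
    """Continuous-compounding-free discount factor ``(1+r)^(-t/365.25)``.

    Parameters
    ----------
    t_days : array-like
        Time of accrual in days from index.
    annual_rate : float
        Annual discount rate, e.g. ``0.015``. Must be nonnegative.
    """
    if annual_rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {annual_rate}")
    return (1.0 + annual_rate) ** (-np.asarray(t_days, dtype=float) / DAYS_PER_YEAR)


def interval_discount_factors(annual_rate: float,
                              horizon_days: int = HORIZON_DAYS,
                              interval_days: int = INTERVAL_DAYS) -> np.ndarray:
    """Per-interval discount factors evaluated at interval midpoints."""
    starts = interval_starts(horizon_days, interval_days)
    widths = interval_widths(horizon_days, interval_days)
    return discount_factor(starts + widths / 2.0, annual_rate)


# ---------------------------------------------------------------------------
# censoring curve
# ---------------------------------------------------------------------------

@dataclass
class CensoringCurve:
    """Reversed Kaplan-Meier probability of remaining uncensored, per arm.

    Attributes
    ----------
    arm : str
        Arm label the curve was estimated on.
    starts : ndarray
        Interval start days ``0, 30, ..., 1800``.
    probabilities : ndarray
        ``K`` at each interval start, left-continuous. ``K(0) == 1`` and the
        sequence is nonincreasing. A trailing run of zeros can only occur
        past the arm's last follow-up (no patient is ever weighted there).
    """

    arm: str
    starts: np.ndarray
    probabilities: np.ndarray
    horizon_days: int = HORIZON_DAYS

    def __post_init__(self):
        k = np.asarray(self.probabilities, float)
        if k[0] != 1.0:
            raise EstimationError("K(0) must equal 1")
        if np.any(np.diff(k) > 1e-12):
            raise EstimationError("censoring curve must be nonincreasing")


def km_censoring_curve(followup_days, is_death,
                       horizon_days: int = HORIZON_DAYS,
                       interval_days: int = INTERVAL_DAYS,
                       arm: str = "",
                       on_zero: str = "error") -> CensoringCurve:
    """Estimate the probability of remaining uncensored at interval starts.

    Censoring (any follow-up end before the horizon that is not a death) is
    the Kaplan-Meier event; deaths leave the risk set without an event.
    Reaching the horizon alive is not a censoring event before the horizon
    and therefore never reduces ``K`` on the grid.

    Parameters
    ----------
    followup_days, is_death : array-like
        Follow-up end (days) and death indicator per patient.
    on_zero : {"error", "allow"}
        If ``K`` reaches 0 at a grid start before the horizon, ``"error"``
        (the default) raises :class:`EstimationError` advising horizon
        truncation, because mean estimation beyond that point is not
        identified; ``"allow"`` returns the curve with its zero tail (no
        patient has observation time there, so no weight is ever undefined).
    """
    fu = np.asarray(followup_days, dtype=float)
    death = np.asarray(is_death, dtype=bool)
    if fu.size == 0:
        raise DegenerateArmError(f"arm {arm!r}: no patients")
    if np.any(fu < 0):
        raise ValidationError("follow-up times must be nonnegative")

    censored = ~death & (fu < horizon_days)
    if np.all(~death & (fu < interval_days)):
        raise DegenerateArmError(
            f"arm {arm!r}: every patient is censored within the first "
            f"interval; censoring weights are undefined"
        )

    starts = interval_starts(horizon_days, interval_days)
    # product-limit over censoring event times, death-first at ties:
    # at a censoring time t the risk set is everyone with follow-up beyond t
    # plus the patients censored exactly at t (deaths at t have left).
    times, d = np.unique(fu[censored], return_counts=True)
    if times.size == 0:
        k = np.ones_like(starts)
    else:
        fu_sorted = np.sort(fu)
        beyond = fu.size - np.searchsorted(fu_sorted, times, side="right")
        factors = 1.0 - d / (beyond + d)
        surv = np.cumprod(factors)
        # K(s) is left-continuous: apply factors of events strictly before s
        idx = np.searchsorted(times, starts, side="left")
        k = np.where(idx > 0, surv[np.maximum(idx - 1, 0)], 1.0)
        k = np.clip(k, 0.0, 1.0)

    if on_zero == "error" and np.any(k <= 0):
        first = starts[np.argmax(k <= 0)]
        raise EstimationError(
            f"arm {arm!r}: probability of remaining uncensored reaches 0 at "
            f"day {first:.0f}, before the {horizon_days}-day horizon; the "
            f"mean is not identified there — truncate the horizon or revisit "
            f"the censoring pattern"
        )
    elif on_zero not in ("error", "allow"):
        raise ValidationError(f"on_zero must be 'error' or 'allow', got {on_zero!r}")
    return CensoringCurve(arm=arm, starts=starts, probabilities=k,
                          horizon_days=horizon_days)


# ---------------------------------------------------------------------------
# partitioning and weighting
# ---------------------------------------------------------------------------

def partition_followup(followup_days,
                       horizon_days: int = HORIZON_DAYS,
                       interval_days: int = INTERVAL_DAYS) -> np.ndarray:
    """Observed days in each interval: overlap of the interval with follow-up.

    Accepts a scalar or a vector of follow-up ends; returns an
    ``(n, n_intervals)`` matrix (``(1, n_intervals)`` for a scalar).
    """
    fu = np.atleast_1d(np.asarray(followup_days, dtype=float))
    if np.any(fu > horizon_days):
        raise ValidationError("follow-up end must not exceed the horizon")
    starts = interval_starts(horizon_days, interval_days)
    widths = interval_widths(horizon_days, interval_days)
    return np.clip(fu[:, None] - starts[None, :], 0.0, widths[None, :])


def ipcw_weight_matrix(followup_days, is_death, curve: CensoringCurve,
                       include_partial: bool = False) -> np.ndarray:
    """Per-patient, per-interval IPCW weights ``1/K(start)`` where observed.

    A patient is weighted in an interval when under observation at its start
    and not censored within it: fully observed intervals always count, the
    interval containing a death counts (the death is an outcome, not a loss
    of observation), and the interval containing a censoring event counts
    only under ``include_partial=True``. All other intervals get weight 0.
    """
    fu = np.asarray(followup_days, dtype=float)
    death = np.asarray(is_death, dtype=bool)
    starts = curve.starts
    step = starts[1] - starts[0] if len(starts) > 1 else float(curve.horizon_days)
    ends = np.minimum(starts + step, curve.horizon_days)
    full = fu[:, None] >= ends[None, :]
    partial = (fu[:, None] > starts[None, :]) & ~full
    mask = full | (partial & death[:, None])
    if include_partial:
        mask = mask | partial

    k = curve.probabilities
    if np.any(mask & (k[None, :] <= 0)):
        raise EstimationError(
            "IPCW weight required where the censoring probability is 0"
        )
    inv = np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), 0.0)
    return mask * inv[None, :]


def ipcw_adjust(contributions: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Apply IPCW weights to per-interval contributions (elementwise)."""
    contributions = np.asarray(contributions, dtype=float)
    if contributions.shape != weights.shape:
        raise ValidationError(
            f"contribution shape {contributions.shape} does not match "
            f"weight shape {weights.shape}"
        )
    return contributions * weights


def discount(contributions: np.ndarray, annual_rate: float,
             horizon_days: int = HORIZON_DAYS,
             interval_days: int = INTERVAL_DAYS) -> np.ndarray:
    """Discount per-interval contributions at the interval midpoints.

    Returns the discounted totals (summed over intervals) per patient.
    """
    d = interval_discount_factors(annual_rate, horizon_days, interval_days)
    contributions = np.atleast_2d(np.asarray(contributions, dtype=float))
    return contributions @ d


# ---------------------------------------------------------------------------
# composite per-patient adjusted outcomes
# ---------------------------------------------------------------------------

def adjusted_outcomes(cohort: pd.DataFrame,
                      cost_matrices: dict,
                      discount_rate: float = 0.015,
                      horizon_days: int = HORIZON_DAYS,
                      interval_days: int = INTERVAL_DAYS,
                      include_partial: bool = False,
                      utilities=None,
                      curves: dict | None = None,
                      on_zero: str = "error") -> pd.DataFrame:
    """IPCW-adjusted, discounted five-year outcomes for every patient.

    Parameters
    ----------
    cohort : DataFrame
        One row per patient with at least ``patient_id``, ``arm``,
        ``followup_days``, ``death`` and — when QALYs are requested —
        ``secondline_end_day``/``thirdline_start_day`` for the health-state
        timeline.
    cost_matrices : dict
        Mapping ``category -> (n, n_intervals)`` cost array aligned with the
        cohort rows; the key ``"drug_of_interest"`` holds the tagged drug
        acquisition cost (a within-``systemic_therapy`` subset kept separate
        so price-reduction analyses can target it).
    utilities : tuple or None
        ``(pf_utility, progressed_utility)`` per patient (arrays or
        scalars). When given, a ``qaly`` column is produced from the
        health-state timeline; otherwise ``qaly`` is NaN.
    curves : dict or None
        Pre-estimated per-arm :class:`CensoringCurve`; estimated from the
        cohort when omitted.

    Returns
    -------
    DataFrame with columns ``patient_id, arm, ly, qaly, cost_total,
    cost_drug_of_interest`` and one ``cost_<category>`` column per ledger
    category (drug cost included in ``cost_systemic_therapy``).
    """
    n = len(cohort)
    fu = cohort["followup_days"].to_numpy(dtype=float)
    death = cohort["death"].to_numpy(dtype=bool)
    arm = cohort["arm"].to_numpy()

    obs = partition_followup(fu, horizon_days, interval_days)
    dfac = interval_discount_factors(discount_rate, horizon_days, interval_days)

    weights = np.zeros_like(obs)
    for a in ARMS:
        sel = arm == a
        if not sel.any():
            continue
        if curves is not None and a in curves:
            curve = curves[a]
        else:
            curve = km_censoring_curve(
                fu[sel], death[sel], horizon_days, interval_days,
                arm=a, on_zero=on_zero,
            )
        weights[sel] = ipcw_weight_matrix(fu[sel], death[sel], curve,
                                          include_partial=include_partial)

    ly_int = ipcw_adjust(obs, weights)          # adjusted days per interval
    ly = (ly_int * dfac) @ np.ones(obs.shape[1]) / DAYS_PER_YEAR

    out = pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy(),
        "arm": arm,
        "ly": ly,
    })

    if utilities is not None:
        from . import qaly as _qaly  # deferred: qaly imports this module's grid
        pf_frac = _qaly.pf_fraction_matrix(cohort, horizon_days, interval_days)
        u_pf, u_prog = utilities
        u_pf = np.broadcast_to(np.asarray(u_pf, dtype=float), (n,))
        u_prog = np.broadcast_to(np.asarray(u_prog, dtype=float), (n,))
        util = u_pf[:, None] * pf_frac + u_prog[:, None] * (1.0 - pf_frac)
        out["qaly"] = ((ly_int * util) * dfac) @ np.ones(obs.shape[1]) / DAYS_PER_YEAR
    else:
        out["qaly"] = np.nan

    total = np.zeros(n)
    for cat in COST_CATEGORIES:
        mat = cost_matrices.get(cat)
        if mat is None:
            adj = np.zeros(n)
        else:
            if mat.shape != obs.shape:
                raise ValidationError(
                    f"cost matrix {cat!r} has shape {mat.shape}, "
                    f"expected {obs.shape}"
                )
            adj = (ipcw_adjust(mat, weights) * dfac) @ np.ones(obs.shape[1])
        out[f"cost_{cat}"] = adj
        total += adj
    drug = cost_matrices.get("drug_of_interest")
    if drug is not None:
        drug_adj = (ipcw_adjust(drug, weights) * dfac) @ np.ones(obs.shape[1])
    else:
        drug_adj = np.zeros(n)
    out["cost_drug_of_interest"] = drug_adj
    out["cost_systemic_therapy"] = out["cost_systemic_therapy"] + drug_adj
    out["cost_total"] = total + drug_adj
    return out
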