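"""Health-state timelines and utility-weighted QALY computation.

Each patient's observed survival is split into two health states:

* **progression-free** — from index until progression;
* **progressed** — from the earliest progression trigger onward. The
  triggers are (a) the start of third-line treatment, and (b) for decedents
  without third-line treatment, the later of the end of second-line
  treatment and six months (182.625 days) before death. Patients surviving
  less than six months are therefore progression-free only while on
  second-line treatment — the pre-death window rule collapses onto the end
  of second-line treatment for them. Patients alive at censoring or at the
  horizon with no third-line treatment remain progression-free throughout.

Utilities are sampled from beta distributions parameterized by method of
moments: the progression-free utility directly, and the progressed utility
as progression-free minus an independently sampled disutility, floored at
zero. Within a probabilistic (bootstrap) analysis, utilities are sampled
once per patient per replicate; point estimates use the distribution means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    DAYS_PER_YEAR,
    HORIZON_DAYS,
    INTERVAL_DAYS,
    SIX_MONTHS_DAYS,
    UtilityParams,
)
from .censoring import interval_starts, interval_widths, interval_discount_factors
from .exceptions import ValidationError


def beta_from_moments(mean: float, sd: float) -> tuple:
    """Beta shape parameters ``(alpha, beta)`` matching a mean and SD.

    Uses ``alpha = mean * nu``, ``beta = (1 - mean) * nu`` with
    ``nu = mean (1 - mean) / sd^2 - 1``. The variance must be strictly
    smaller than ``mean (1 - mean)`` for a beta distribution to exist.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must lie in (0,1), got {mean}")
    if sd <= 0:
        raise ValidationError(f"beta sd must be > 0, got {sd}")
    if sd * sd >= mean * (1.0 - mean):
        raise ValidationError(
            f"variance {sd**2:.4g} too large for a beta distribution with "
            f"mean {mean} (must be < {mean * (1 - mean):.4g})"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def progression_start(cohort: pd.DataFrame) -> np.ndarray:
    """Day each patient enters the progressed state (NaN = never observed).

    Implements the two progression triggers described in the module
    docstring, clamped into ``[0, followup_days]``.
    """
    fu = cohort["followup_days"].to_numpy(dtype=float)
    death = cohort["death"].to_numpy(dtype=bool)
    sl_end = cohort["secondline_end_day"].to_numpy(dtype=float)
    t3 = cohort["thirdline_start_day"].to_numpy(dtype=float)  # NaN if none

    if np.any(sl_end - fu > 1e-9):
        raise ValidationError("second-line end must not exceed follow-up end")
    if np.any(t3[np.isfinite(t3)] < 0):
        raise ValidationError("third-line start must be nonnegative")

    pre_death = np.where(death, np.maximum(sl_end, fu - SIX_MONTHS_DAYS), np.inf)
    prog = np.fmin(np.where(np.isfinite(t3), t3, np.inf), pre_death)
    prog = np.clip(prog, 0.0, None)
    prog[~np.isfinite(prog)] = np.nan
    return prog


def partition_health_states(cohort: pd.DataFrame) -> pd.DataFrame:
    """Explicit state timelines: contiguous segments covering follow-up.

    Returns one or two rows per patient with columns
    ``patient_id, state, start_day, end_day``; states are
    ``progression_free`` then ``progressed``.
    """
    prog = progression_start(cohort)
    rows = []
    for pid, fu, p in zip(cohort["patient_id"], cohort["followup_days"], prog):
        if np.isnan(p) or p >= fu:
            rows.append((pid, "progression_free", 0.0, float(fu)))
        elif p <= 0:
            rows.append((pid, "progressed", 0.0, float(fu)))
        else:
            rows.append((pid, "progression_free", 0.0, float(p)))
            rows.append((pid, "progressed", float(p), float(fu)))
    return pd.DataFrame(rows, columns=["patient_id", "state", "start_day", "end_day"])


def pf_fraction_matrix(cohort: pd.DataFrame,
                       horizon_days: int = HORIZON_DAYS,
                       interval_days: int = INTERVAL_DAYS) -> np.ndarray:
    """Progression-free share of each patient's observed time per interval.

    For intervals straddling the progression time the share is the
    time-weighted fraction, so interval utilities are time-weighted averages
    of the two state utilities. Intervals with no observed time get 1
    (irrelevant: they carry zero life-years).
    """
    fu = cohort["followup_days"].to_numpy(dtype=float)
    prog = progression_start(cohort)
    prog_eff = np.where(np.isnan(prog), np.inf, prog)

    starts = interval_starts(horizon_days, interval_days)
    widths = interval_widths(horizon_days, interval_days)
    obs = np.clip(fu[:, None] - starts[None, :], 0.0, widths[None, :])
    pf_days = np.clip(np.minimum(prog_eff, fu)[:, None] - starts[None, :],
                      0.0, widths[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(obs > 0, pf_days / np.where(obs > 0, obs, 1.0), 1.0)
    return frac


def sample_utilities(n_patients: int, params: UtilityParams,
                     rng: np.random.Generator) -> tuple:
    """One utility draw per patient: ``(pf_utility, progressed_utility)``.

    The progression-free utility and the disutility are independent
    moment-matched beta draws; the progressed utility is their difference
    floored at zero. Draws are independent across patients.
    """
    params.validate()
    a_pf, b_pf = beta_from_moments(params.pf_mean, params.pf_sd)
    a_d, b_d = beta_from_moments(params.disutility_mean, params.disutility_sd)
    u_pf = rng.beta(a_pf, b_pf, size=n_patients)
    disutil = rng.beta(a_d, b_d, size=n_patients)
    u_prog = np.maximum(u_pf - disutil, 0.0)
    return u_pf, u_prog


def mean_utilities(params: UtilityParams) -> tuple:
    """Point-estimate utilities: distribution means ``(pf, pf - disutility)``."""
    params.validate()
    return params.pf_mean, max(params.pf_mean - params.disutility_mean, 0.0)


def qaly_from_timeline(cohort: pd.DataFrame,
                       utilities,
                       adjusted_ly_days: np.ndarray,
                       discount_rate: float = 0.0,
                       horizon_days: int = HORIZON_DAYS,
                       interval_days: int = INTERVAL_DAYS) -> np.ndarray:
    """Utility-weight per-interval adjusted life-days into QALYs (years).

    ``adjusted_ly_days`` is an ``(n, n_intervals)`` matrix of (typically
    IPCW-adjusted) observed days. Each interval is multiplied by its
    time-weighted state utility and the midpoint discount factor, then
    summed and converted to years.
    """
    adjusted_ly_days = np.asarray(adjusted_ly_days, dtype=float)
    n_int = len(interval_starts(horizon_days, interval_days))
    if adjusted_ly_days.shape != (len(cohort), n_int):
        raise ValidationError(
            f"adjusted life-day matrix has shape {adjusted_ly_days.shape}, "
            f"expected {(len(cohort), n_int)}"
        )
    frac = pf_fraction_matrix(cohort, horizon_days, interval_days)
    u_pf, u_prog = utilities
    u_pf = np.broadcast_to(np.asarray(u_pf, dtype=float), (len(cohort),))
    u_prog = np.broadcast_to(np.asarray(u_prog, dtype=float), (len(cohort),))
    util = u_pf[:, None] * frac + u_prog[:, None] * (1.0 - frac)
    dfac = interval_discount_factors(discount_rate, horizon_days, interval_days)
    return (adjusted_ly_days * util * dfac).sum(axis=1) / DAYS_PER_YEAR
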