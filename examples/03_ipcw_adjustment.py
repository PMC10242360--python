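"""Censoring adjustment with the partitioned IPCW estimator.

Shows the estimator's mechanics on the canonical three-patient example
(deaths at days 45 and 100, censoring at day 75), then applies it to a
simulated cohort: per-arm reversed Kaplan-Meier censoring curves, 30-day
partitioning, inverse weighting and 1.5% discounting, producing per-patient
censor-adjusted five-year life-years, QALYs and costs.
"""

import numpy as np

import rwcea
from rwcea.censoring import (
    km_censoring_curve, ipcw_weight_matrix, partition_followup,
)
from rwcea.simulate import cost_matrices

# -- the hand-checkable miniature ------------------------------------------
fu = np.array([45.0, 75.0, 100.0])
death = np.array([True, False, True])
curve = km_censoring_curve(fu, death)
print("K at interval starts 0/30/60/90:", curve.probabilities[:4])
adj = (partition_followup(fu) * ipcw_weight_matrix(fu, death, curve)).sum(1)
print("adjusted survival days per patient:", adj,
      f"-> arm mean {adj.mean():.2f} d (= 215/3; the censored patient "
      "contributes only its fully observed intervals, the late death is "
      "up-weighted by 1/K)")

# -- a full cohort ----------------------------------------------------------
cfg = rwcea.default_config(seed=7)
cohort = rwcea.generate_cohort(cfg)
mats = cost_matrices(cohort, cfg)
adjusted = rwcea.adjusted_outcomes(cohort, mats, discount_rate=0.015,
                                   utilities=rwcea.mean_utilities(cfg.utilities))
print("\nper-arm censor-adjusted discounted means (unweighted):")
print(adjusted.groupby("arm")[["ly", "qaly", "cost_total"]].mean().round(3))
print("\n(cost columns also available per resource category, e.g. "
      f"systemic therapy: "
      f"{adjusted.groupby('arm')['cost_systemic_therapy'].mean().round(0).to_dict()})")
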