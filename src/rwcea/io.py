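"""Readers, writers, run configuration, and the end-to-end pipeline.

File formats are deliberately plain CSV/YAML/JSON for transparency.

Cohort CSV column dictionary (one row per patient):

=====================  =====================================================
column                 meaning
=====================  =====================================================
patient_id             unique identifier (string)
arm                    "control" or "treated"
age                    years at index
male                   0/1
income_quintile        1-5
urban                  0/1
morbidity_score        aggregated morbidity burden score
adg_count              number of aggregated diagnosis groups
charlson_1plus         0/1, Charlson comorbidity index >= 1
prior_radiation        0/1
prior_resection        0/1
firstline_class        "chemo" / "braf_mek" / "other"
months_dx_to_2l        months from diagnosis to second-line start
followup_days          observed follow-up end, days from index (<= 1826)
death                  1 if follow-up ended in death, else 0 (censoring)
secondline_end_day     end of second-line treatment (<= followup_days)
thirdline_start_day    start of third-line treatment, empty if none
true_death_day         (simulated data only) ground-truth death day
=====================  =====================================================

Ledger CSV: ``patient_id, interval, category, amount, drug_of_interest``
— one row per patient x 30-day interval x resource category with a
positive amount; drug-of-interest acquisition entries are flagged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import (
    ARMS,
    COST_CATEGORIES,
    HORIZON_DAYS,
    INTERVAL_DAYS,
    SimConfig,
    UtilityParams,
    default_config,
)
from .cea import (
    CEAEngine,
    DEFAULT_WTP_GRID,
    bootstrap_cea,
    ceac,
    discount_sensitivity,
    incremental_summary,
    nmb_table,
    price_reduction_curve,
)
from .censoring import adjusted_outcomes
from .exceptions import ConfigurationError, ValidationError
from .qaly import mean_utilities
from .simulate import generate_cohort, generate_cost_ledger, ledger_to_matrices
from .weights import balance_table, compute_iptw, fit_propensity

REQUIRED_COHORT_COLUMNS = (
    "patient_id", "arm", "followup_days", "death",
    "secondline_end_day", "thirdline_start_day",
)
REQUIRED_LEDGER_COLUMNS = (
    "patient_id", "interval", "category", "amount", "drug_of_interest",
)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Row-level problems (duplicate ids, unknown arm, negative or
    inconsistent times) are aggregated and reported together with the
    offending row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: cohort file contains no rows")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")

    problems = []

    dup = df["patient_id"][df["patient_id"].duplicated()]
    for i, pid in dup.items():
        problems.append(f"row {i + 2}: duplicate patient_id {pid!r}")

    bad_arm = ~df["arm"].isin(ARMS)
    for i in df.index[bad_arm]:
        problems.append(f"row {i + 2}: unknown arm {df.at[i, 'arm']!r}")

    for col in ("followup_days", "secondline_end_day"):
        neg = df[col] < 0
        for i in df.index[neg]:
            problems.append(f"row {i + 2}: negative {col} ({df.at[i, col]})")
    over = df["followup_days"] > HORIZON_DAYS
    for i in df.index[over]:
        problems.append(
            f"row {i + 2}: followup_days exceeds the {HORIZON_DAYS}-day horizon")

    if not df["death"].isin([0, 1]).all():
        bad = df.index[~df["death"].isin([0, 1])]
        for i in bad:
            problems.append(f"row {i + 2}: death must be 0 or 1")

    # death (follow-up end) must not precede the end of second-line therapy
    sl_after_fu = df["secondline_end_day"] - df["followup_days"] > 1e-9
    for i in df.index[sl_after_fu]:
        problems.append(
            f"row {i + 2}: secondline_end_day {df.at[i, 'secondline_end_day']} "
            f"is after the follow-up end {df.at[i, 'followup_days']}")

    t3 = df["thirdline_start_day"]
    bad_t3 = t3.notna() & (t3 < 0)
    for i in df.index[bad_t3]:
        problems.append(f"row {i + 2}: negative thirdline_start_day")

    if problems:
        head = problems[:20]
        more = f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""
        raise ValidationError(
            f"{path}: {len(problems)} validation problem(s):\n  "
            + "\n  ".join(head) + more
        )
    return df


def read_ledger(path, cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a cost ledger CSV; validate against a cohort when given."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: ledger file contains no rows")
    missing = [c for c in REQUIRED_LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if cohort is not None:
        # full consistency checks happen in the pivot
        ledger_to_matrices(cohort, df, HORIZON_DAYS, INTERVAL_DAYS)
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``cohort_path``/``ledger_path`` point at input CSVs, or
    ``simulate`` holds a :class:`SimConfig` to generate them in memory.
    """

    cohort_path: str | None = None
    ledger_path: str | None = None
    simulate: SimConfig | None = None
    output_dir: str = "rwcea_output"
    horizon_days: int = HORIZON_DAYS
    interval_days: int = INTERVAL_DAYS
    discount_rate: float = 0.015
    utility_params: UtilityParams = field(default_factory=UtilityParams)
    bootstrap_B: int = 1000
    seed: int = 0
    wtp_grid: tuple = tuple(DEFAULT_WTP_GRID)
    nmb_wtp_values: tuple = (50_000.0, 100_000.0, 150_000.0)
    estimand: str = "ATE"
    stabilized: bool = False
    include_partial: bool = False
    reestimate_weights: bool = True
    discount_rates: tuple = (0.0, 0.015, 0.03)
    price_fractions: tuple = tuple(np.linspace(0, 1, 11))
    effect_measure: str = "ly"
    on_zero: str = "error"
    make_plots: bool = True

    def validate(self) -> None:
        has_files = self.cohort_path is not None and self.ledger_path is not None
        if has_files == (self.simulate is not None):
            raise ConfigurationError(
                "exactly one of (cohort_path + ledger_path) or simulate "
                "must be provided")
        if has_files:
            for p in (self.cohort_path, self.ledger_path):
                if not Path(p).exists():
                    raise ConfigurationError(f"input file not found: {p}")
        if self.bootstrap_B < 2:
            raise ConfigurationError("bootstrap_B must be >= 2")
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")


def _config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["wtp_grid"] = list(map(float, d["wtp_grid"]))
    d["price_fractions"] = list(map(float, d["price_fractions"]))
    return d


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(_config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` (optionally nesting a SimConfig) from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    util = raw.pop("utility_params", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        cfg.simulate = sim_config_from_dict(sim)
    if util is not None:
        cfg.utility_params = UtilityParams(**util)
    return cfg


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain-dict (YAML) representation.

    Only scalar-level overrides of the default configuration are supported
    from YAML (arm sizes, seed, censoring window, drug cost, ...); nested
    distribution families are configured in Python.
    """
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown SimConfig field(s) in YAML: {sorted(unknown)}")
    scalars = {k: v for k, v in d.items()
               if not isinstance(v, dict)}
    return default_config(**scalars)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Stages: load or simulate inputs; fit the propensity model and IPTW
    weights; balance table; per-arm censoring curves and IPCW-adjusted
    outcomes; incremental point estimate; stratified bootstrap with CE
    plane, CEAC and ICER CIs; net-benefit regression at the configured
    thresholds; discount-rate and price-reduction sensitivity analyses;
    plots and a JSON metadata sidecar. Deterministic given the seed.

    Returns a dict of the in-memory results keyed by artifact name.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        ledger = generate_cost_ledger(cohort, config.simulate)
        write_cohort(cohort, outdir / "cohort.csv")
        write_ledger(ledger, outdir / "ledger.csv")
    else:
        cohort = read_cohort(config.cohort_path)
        ledger = read_ledger(config.ledger_path, cohort)
    mats = ledger_to_matrices(cohort, ledger, config.horizon_days,
                              config.interval_days)

    fit = fit_propensity(cohort)
    wv = compute_iptw(fit, estimand=config.estimand,
                      stabilized=config.stabilized)
    bal = balance_table(cohort, wv)
    bal.to_csv(outdir / "balance_table.csv", index=False)

    adjusted = adjusted_outcomes(
        cohort, mats, discount_rate=config.discount_rate,
        horizon_days=config.horizon_days, interval_days=config.interval_days,
        include_partial=config.include_partial,
        utilities=mean_utilities(config.utility_params),
        on_zero=config.on_zero,
    )
    adjusted.to_csv(outdir / "adjusted_outcomes.csv", index=False)

    engine_opts = dict(
        discount_rate=config.discount_rate,
        horizon_days=config.horizon_days,
        interval_days=config.interval_days,
        utility_params=config.utility_params,
        estimand=config.estimand,
        stabilized=config.stabilized,
        include_partial=config.include_partial,
        reestimate_weights=config.reestimate_weights,
        on_zero=config.on_zero,
    )
    boot = bootstrap_cea(cohort, mats, B=config.bootstrap_B,
                         seed=config.seed, **engine_opts)
    point = boot.point
    incr = incremental_summary(adjusted, wv)
    incr.ci = point.ci

    _write_incremental_table(incr, outdir / "incremental_summary.csv")
    pd.DataFrame({"dc": boot.dc, "de_ly": boot.de_ly,
                  "de_qaly": boot.de_qaly}).to_csv(
        outdir / "bootstrap_replicates.csv", index=False)

    curve = ceac(boot, np.asarray(config.wtp_grid), config.effect_measure)
    pd.DataFrame({"wtp": curve.wtp, "probability": curve.probability}).to_csv(
        outdir / "ceac.csv", index=False)

    nmb = nmb_table(adjusted, wv, config.nmb_wtp_values, config.effect_measure)
    nmb.to_csv(outdir / "nmb_table.csv", index=False)

    sens_disc = discount_sensitivity(cohort, mats, rates=config.discount_rates,
                                     B=config.bootstrap_B, seed=config.seed,
                                     **{k: v for k, v in engine_opts.items()
                                        if k != "discount_rate"})
    sens_disc.to_csv(outdir / "discount_sensitivity.csv", index=False)

    price = price_reduction_curve(cohort, mats,
                                  fractions=np.asarray(config.price_fractions),
                                  **engine_opts)
    price.to_csv(outdir / "price_reduction.csv", index=False)

    if config.make_plots:
        from . import plots
        plots.ce_plane(boot, config.effect_measure,
                       path=outdir / "ce_plane.png")
        plots.ceac_plot(curve, path=outdir / "ceac.png")
        plots.price_reduction_plot(price, path=outdir / "price_reduction.png")

    meta = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": _config_to_dict(config),
        "n_patients": int(len(cohort)),
        "arm_sizes": cohort["arm"].value_counts().to_dict(),
        "weighted_n": wv.weighted_n,
        "bootstrap_redrawn": boot.n_redrawn,
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)

    return {
        "cohort": cohort, "ledger": ledger, "weights": wv, "balance": bal,
        "adjusted": adjusted, "incremental": incr, "bootstrap": boot,
        "ceac": curve, "nmb": nmb, "discount_sensitivity": sens_disc,
        "price_reduction": price, "metadata": meta,
    }


def _write_incremental_table(incr, path) -> None:
    """Report-style incremental table: one row per outcome, CI where known."""
    rows = []

    def ci_str(key):
        ci = incr.ci.get(key) if incr.ci else None
        return (ci[0], ci[1]) if ci is not None else (np.nan, np.nan)

    lo, hi = ci_str("incremental_cost")
    rows.append(("mean_total_cost", incr.arm_means["cost_total"]["control"],
                 incr.arm_means["cost_total"]["treated"],
                 incr.incremental_cost, lo, hi))
    for cat in COST_CATEGORIES:
        m = incr.arm_means[f"cost_{cat}"]
        rows.append((f"cost_{cat}", m["control"], m["treated"],
                     m["treated"] - m["control"], np.nan, np.nan))
    lo, hi = ci_str("incremental_ly")
    rows.append(("mean_ly", incr.arm_means["ly"]["control"],
                 incr.arm_means["ly"]["treated"], incr.incremental_ly, lo, hi))
    lo, hi = ci_str("incremental_qaly")
    rows.append(("mean_qaly", incr.arm_means["qaly"]["control"],
                 incr.arm_means["qaly"]["treated"], incr.incremental_qaly,
                 lo, hi))
    lo, hi = ci_str("icer_per_ly")
    rows.append(("icer_per_ly", np.nan, np.nan,
                 incr.icer_per_ly if incr.icer_per_ly is not None else np.nan,
                 lo, hi))
    lo, hi = ci_str("icer_per_qaly")
    rows.append(("icer_per_qaly", np.nan, np.nan,
                 incr.icer_per_qaly if incr.icer_per_qaly is not None else np.nan,
                 lo, hi))
    pd.DataFrame(rows, columns=["outcome", "control", "treated",
                                "incremental", "ci_low", "ci_high"]
                 ).to_csv(path, index=False)
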