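"""Simulation-study driver: design bias, design variance and coverage.

Each replicate generates one cohort, fits the full-cohort model, draws the
standard and modified NCC samples with coupled randomness (so the standard
sample is nested in the modified one and design comparisons are paired) and
computes all requested estimator/design combinations of the log-relative
hazards and the cumulative baseline hazard over a reporting interval.

Summary metrics across replicates, relative to the paired full-cohort fits:

* design bias   DB = |mean(theta_ncc) - mean(theta_full)|
* design variance DV = var(theta_ncc) - var(theta_full)   (divisor B-1)
* efficiency ratio R = DV_standard / DV_modified
* SD (empirical), SE (mean estimated standard error) and CR (coverage of
  nominal-level Wald intervals around the truth).

DV can come out slightly negative at small B; it is reported as-is with a
flag rather than truncated, since truncation would bias R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import breslow_ipw, breslow_lb, fit_conditional, fit_cox, fit_ipw
from .inclusion import compute_weights, full_cohort_weights
from .sampling import sample_coupled
from .simulate import SimConfig, generate_cohort
from .variance import (
    influence_functions,
    interval_hazard_if,
    lb_hazard_variance,
    variance_estimate,
    wald_ci,
)

__all__ = [
    "ScenarioConfig",
    "SimStudyResult",
    "run_replicate",
    "design_bias",
    "design_variance",
    "design_variance_ratio",
    "coverage_rate",
    "run_simulation_study",
]


@dataclass
class ScenarioConfig:
    """One simulation scenario: a generative cell plus the design grid."""

    sim: SimConfig
    m_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    designs: tuple[str, ...] = ("standard", "modified")
    estimators: tuple[str, ...] = ("conditional", "ipw")
    B: int = 200
    tau_interval: tuple[float, float] = (0.0, 10.0)
    level: float = 0.95
    compute_se: bool = True
    ipw_design_se: bool = True  # the O(n^2) pair term; switch off for speed
    scenario_id: int = 0

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if any(m < 1 for m in self.m_values):
            raise ValueError("m values must be positive")


def _replicate_rng(master_seed, scenario_id: int, b: int) -> np.random.Generator:
    """Independent, reproducible substream for replicate b of a scenario."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), scenario_id, b]))


def run_replicate(config: ScenarioConfig, b: int, master_seed=None) -> list[dict]:
    """One cohort -> full fit plus all NCC estimator/design cells.

    Returns long-format rows; raises nothing on its own, non-convergence
    propagates with the replicate id attached by the study driver.
    """
    seed = config.sim.seed if master_seed is None else master_seed
    rng = _replicate_rng(seed if seed is not None else 0, config.scenario_id, b)
    sim = generate_cohort(config.sim, rng)
    cohort = sim.cohort
    tau0, tau1 = config.tau_interval
    rows: list[dict] = []

    def emit(estimator, design, m, beta, lam, beta_se=None, lam_se=None):
        p = len(beta)
        for j in range(p):
            rows.append(
                dict(replicate=b, estimator=estimator, design=design, m=m,
                     param=f"beta{j + 1}", estimate=float(beta[j]),
                     se=None if beta_se is None else float(beta_se[j]))
            )
        rows.append(
            dict(replicate=b, estimator=estimator, design=design, m=m,
                 param="Lambda0", estimate=float(lam),
                 se=None if lam_se is None else float(lam_se))
        )

    full_fit = fit_cox(cohort)
    full_lam = breslow_ipw(full_fit).cumulative(tau0, tau1)
    if config.compute_se:
        fw = full_cohort_weights(cohort)
        infl = influence_functions(cohort, full_fit, fw)
        lam_if = interval_hazard_if(infl, tau0, tau1)
        ve = variance_estimate(
            np.column_stack([infl.if_beta, lam_if]), fw, cohort.n
        )
        emit("full", "full", 0, full_fit.beta, full_lam, ve.se[:-1], ve.se[-1])
    else:
        emit("full", "full", 0, full_fit.beta, full_lam)

    for m in config.m_values:
        std, mod = sample_coupled(cohort, m, rng=rng)
        for sample in (std, mod):
            if sample.design not in config.designs:
                continue
            if "conditional" in config.estimators:
                cfit = fit_conditional(cohort, sample)
                lb = breslow_lb(cohort, sample, cfit.beta)
                lam = lb.cumulative(tau0, tau1)
                if config.compute_se:
                    beta_se = np.sqrt(np.diag(cfit.cov))
                    lam_se = np.sqrt(lb_hazard_variance(cohort, sample, cfit, tau0, tau1))
                    emit("conditional", sample.design, m, cfit.beta, lam, beta_se, lam_se)
                else:
                    emit("conditional", sample.design, m, cfit.beta, lam)
            if "ipw" in config.estimators:
                w = compute_weights(cohort, sample)
                sfit = fit_ipw(cohort, sample, w)
                lam = breslow_ipw(sfit).cumulative(tau0, tau1)
                if config.compute_se and config.ipw_design_se:
                    infl = influence_functions(cohort, sfit, w)
                    lam_if = interval_hazard_if(infl, tau0, tau1)
                    ve = variance_estimate(
                        np.column_stack([infl.if_beta, lam_if]), w, cohort.n
                    )
                    emit("ipw", sample.design, m, sfit.beta, lam, ve.se[:-1], ve.se[-1])
                else:
                    emit("ipw", sample.design, m, sfit.beta, lam)
    return rows


def design_bias(ncc_estimates, full_estimates) -> float:
    """|mean(ncc) - mean(full)| over paired replicates."""
    ncc = np.asarray(ncc_estimates, float)
    full = np.asarray(full_estimates, float)
    if ncc.shape != full.shape:
        raise ValueError("replicate vectors differ in length")
    return float(abs(ncc.mean() - full.mean()))


def design_variance(ncc_estimates, full_estimates) -> float:
    """var(ncc) - var(full), empirical variances with divisor B-1."""
    ncc = np.asarray(ncc_estimates, float)
    full = np.asarray(full_estimates, float)
    if ncc.shape != full.shape:
        raise ValueError("replicate vectors differ in length")
    if ncc.size < 2:
        raise ValueError("need at least two replicates")
    return float(ncc.var(ddof=1) - full.var(ddof=1))


def design_variance_ratio(dv_standard: float, dv_modified: float) -> float | None:
    """R = DV_std / DV_mod; None (flagged) when either DV is non-positive."""
    if dv_standard <= 0 or dv_modified <= 0:
        return None
    return float(dv_standard / dv_modified)


def coverage_rate(estimates, ses, truth: float, level: float = 0.95) -> float:
    """Fraction of replicates whose Wald interval covers the truth."""
    estimates = np.asarray(estimates, float)
    ses = np.asarray(ses, float)
    hits = 0
    for est, se in zip(estimates, ses):
        lo, hi = wald_ci(est, se, level)
        hits += lo <= truth <= hi
    return hits / len(estimates)


@dataclass
class SimStudyResult:
    """Per-replicate estimates and the summary metric table."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    config: ScenarioConfig = field(repr=False)


def run_simulation_study(
    config: ScenarioConfig, master_seed=None, progress: bool = False
) -> SimStudyResult:
    """Run B replicates and aggregate DB / DV / R / SD / SE / CR per cell."""
    all_rows: list[dict] = []
    failures: list[tuple[int, str]] = []
    for b in range(config.B):
        try:
            all_rows.extend(run_replicate(config, b, master_seed))
        except ValueError as err:  # non-convergence etc.: record, keep going
            failures.append((b, str(err)))
        if progress and (b + 1) % 25 == 0:
            print(f"  replicate {b + 1}/{config.B}")
    reps = pd.DataFrame(all_rows)
    if failures:
        reps.attrs["failures"] = failures
    summary = summarize_study(reps, config)
    return SimStudyResult(replicates=reps, summary=summary, config=config)


def _truth(config: ScenarioConfig, param: str) -> float:
    if param.startswith("beta"):
        return config.sim.beta[int(param[4:]) - 1]
    tau0, tau1 = config.tau_interval
    lo = max(tau0, 0.0)
    hi = min(tau1, config.sim.tau_end)
    return config.sim.lambda0 * max(hi - lo, 0.0)


def summarize_study(replicates: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Recompute all summary metrics from the per-replicate table."""
    rows = []
    full = replicates[replicates.estimator == "full"]
    for (estimator, design, m, param), cell in replicates.groupby(
        ["estimator", "design", "m", "param"]
    ):
        if estimator == "full":
            continue
        fcell = full[full.param == param].set_index("replicate")["estimate"]
        cell = cell.set_index("replicate")
        common = cell.index.intersection(fcell.index)
        est = cell.loc[common, "estimate"].to_numpy()
        fest = fcell.loc[common].to_numpy()
        truth = _truth(config, param)
        row = dict(
            estimator=estimator, design=design, m=m, param=param, B=len(common),
            mean=est.mean(), sd=est.std(ddof=1),
            db=design_bias(est, fest), dv=design_variance(est, fest),
        )
        row["dv_negative"] = row["dv"] < 0
        ses = cell.loc[common, "se"]
        if ses.notna().all():
            row["se"] = float(ses.mean())
            row["cr"] = coverage_rate(est, ses.to_numpy(float), truth, config.level)
        rows.append(row)
    summary = pd.DataFrame(rows)
    if summary.empty:
        return summary
    # pair std/mod design variances into the efficiency ratio R
    ratios = []
    for (estimator, m, param), cell in summary.groupby(["estimator", "m", "param"]):
        by_design = cell.set_index("design")["dv"]
        if {"standard", "modified"} <= set(by_design.index):
            r = design_variance_ratio(by_design["standard"], by_design["modified"])
            ratios.append(
                dict(estimator=estimator, m=m, param=param,
                     ratio=np.nan if r is None else r)
            )
    if ratios:
        summary = summary.merge(pd.DataFrame(ratios), on=["estimator", "m", "param"], how="left")
    return summary
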