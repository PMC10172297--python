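"""Config-driven simulation studies and application-style reports.

Each runner reproduces one of the framework's study designs on a synthetic
pool: validating Algorithm-1 estimates against empirical truth, sweeping
the overall event rate or the between-hospital variance, probing
risk-adjustment misspecification (over- and underfitting), and producing
the per-hospital accuracy report with threshold summaries.  Every runner
is reproducible from (spec, seed) and returns plain DataFrames; the CLI
writes them as CSV with a JSON provenance sidecar.

Default replication counts are desk-scale (empirical truth from 2,000
replications, 20 Algorithm-1 estimate runs at K = 1,000) with the
associated Monte-Carlo error documented in the methods note; full-scale
counts are a parameter away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .accuracy import (
    QuartileAccuracySimulator,
    flag_upper_quartile,
    min_events_for_target,
    simulate_classification_counts,
    simulate_dataset,
)
from .cohort import CohortTable, summarize_by_hospital
from .glmm import ConditionalParams, attenuate, fit_conditional, fit_marginal
from .synthetic import (
    CohortGenerator,
    GeneratorConfig,
    extended_covariates,
    resample_within_hospital,
)

__all__ = [
    "ScenarioSpec",
    "run_validate_algorithm",
    "run_event_rate_sweep",
    "run_sigma_sweep",
    "run_misspecification",
    "run_application_report",
    "write_report",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a scenario run."""

    kind: str = "validate_algorithm"
    rates: tuple[float, ...] = (0.03, 0.05, 0.10, 0.15, 0.20, 0.30, 0.50)
    sigmas: tuple[float, ...] = (0.5, 0.75, 1.0)
    n_datasets: int = 1000  # K inside Algorithm 1
    truth_replicates: int = 2000  # empirical-truth replications
    n_estimates: int = 20  # Algorithm-1 estimate runs for validation
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    common_random_numbers: bool = False

    def provenance(self) -> dict:
        d = asdict(self)
        gen = d.pop("generator")
        gen.pop("correlation", None)
        gen["covariates"] = [c["name"] for c in gen["covariates"]]
        d["generator"] = gen
        return d


def _empirical_truth(covs: CohortTable, params: ConditionalParams, n_rep: int, seed_seq) -> pd.DataFrame:
    """Empirical Power/FPR/PPV/NPV from independent replications under the
    true parameters, with the SIR model refit per replication."""
    res = simulate_classification_counts(
        covs.covariates, covs.group_index, covs.n_hospitals, params, n_rep, seed_seq
    )
    out = res.estimates(0)
    out.insert(0, "hospital_id", covs.hospital_ids)
    out.insert(1, "volume", covs.volumes)
    out["mean_predicted_events"] = res.mean_predicted[0]
    return out


def run_validate_algorithm(spec: ScenarioSpec) -> dict:
    """Empirical truth vs repeated Algorithm-1 estimates.

    Simulates the observed dataset ``n_estimates`` times; each time
    Algorithm 1 is run in full (conditional-model refit, then K simulated
    datasets).  Returns the truth table, the stacked estimate tables and a
    per-metric mean-absolute-deviation summary.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_pool, ss_truth, ss_obs, ss_est = root.spawn(4)
    pool = CohortGenerator(spec.generator).generate_cohort(
        seed=int(ss_pool.generate_state(1)[0] % 2**31)
    )
    covs = pool.cohort.drop_outcomes()
    truth = _empirical_truth(covs, pool.params, spec.truth_replicates, ss_truth)

    obs_children = ss_obs.spawn(spec.n_estimates)
    est_children = ss_est.spawn(spec.n_estimates)
    estimates = []
    for r in range(spec.n_estimates):
        rng = np.random.default_rng(obs_children[r])
        _, y = simulate_dataset(
            covs.covariates, covs.group_index, covs.n_hospitals, pool.params, rng
        )
        observed = covs.with_outcomes(y)
        cond, _ = fit_conditional(observed)
        sim = QuartileAccuracySimulator(
            n_datasets=spec.n_datasets,
            random_state=int(est_children[r].generate_state(1)[0] % 2**31),
        ).fit_cohort(covs, cond)
        tab = sim.results_.copy()
        tab.insert(0, "replicate", r)
        estimates.append(tab)
    est = pd.concat(estimates, ignore_index=True)

    mad = {}
    for metric in ("power", "fpr", "ppv", "npv"):
        merged = est.merge(truth[["hospital_id", metric]], on="hospital_id", suffixes=("", "_true"))
        d = (merged[metric] - merged[f"{metric}_true"]).abs()
        mad[metric] = float(d.mean())
    return {"truth": truth, "estimates": est, "mad": mad, "pool": pool}


def _sweep_arm(covs, params, n_rep, seed_seq) -> pd.DataFrame:
    tab = _empirical_truth(covs, params, n_rep, seed_seq)
    tab["alpha"] = params.alpha
    tab["sigma_alpha"] = params.sigma_alpha
    return tab


def run_event_rate_sweep(spec: ScenarioSpec) -> pd.DataFrame:
    """Empirical accuracy by surgical volume for a grid of overall event
    rates.  Per arm: covariates are resampled with replacement within each
    hospital (case-mix preserved), the intercept is recalibrated to the
    arm's rate, and outcomes are regenerated."""
    root = np.random.SeedSequence(spec.seed)
    ss_pool, ss_arms = root.spawn(2)
    gen = CohortGenerator(spec.generator)
    pool = gen.generate_cohort(seed=int(ss_pool.generate_state(1)[0] % 2**31))
    base = pool.cohort.drop_outcomes()

    arms = []
    children = ss_arms.spawn(len(spec.rates))
    for rate, child in zip(spec.rates, children):
        rs, rr = child.spawn(2) if not spec.common_random_numbers else (child, child)
        rng = np.random.default_rng(rs)
        covs = resample_within_hospital(base, rng)
        alpha_r = gen.calibrate_intercept(covs, rate)
        params = ConditionalParams(alpha_r, spec.generator.beta, spec.generator.sigma_alpha**2)
        tab = _sweep_arm(covs, params, spec.truth_replicates, rr)
        tab.insert(0, "target_rate", rate)
        arms.append(tab)
    return pd.concat(arms, ignore_index=True)


def run_sigma_sweep(spec: ScenarioSpec) -> pd.DataFrame:
    """Empirical accuracy by surgical volume for a grid of random-effect
    SDs.  The intercept is recalibrated per arm so the overall rate stays
    at the generator's target and only the heterogeneity varies."""
    root = np.random.SeedSequence(spec.seed)
    ss_pool, ss_arms = root.spawn(2)
    gen = CohortGenerator(spec.generator)
    pool = gen.generate_cohort(seed=int(ss_pool.generate_state(1)[0] % 2**31))
    covs = pool.cohort.drop_outcomes()
    rate = spec.generator.target_rate or 0.031

    arms = []
    children = ss_arms.spawn(len(spec.sigmas))
    for sigma, child in zip(spec.sigmas, children):
        alpha_s = gen.calibrate_intercept(covs, rate, sigma_alpha=sigma)
        params = ConditionalParams(alpha_s, spec.generator.beta, sigma**2)
        tab = _sweep_arm(covs, params, spec.truth_replicates, child)
        tab.insert(0, "sigma_alpha_arm", sigma)
        arms.append(tab)
    return pd.concat(arms, ignore_index=True)


def run_misspecification(spec: ScenarioSpec, arm: str = "overfit") -> dict:
    """Paired accuracy under correct and misspecified SIR models.

    ``overfit``: outcomes are generated from the six-covariate truth; SIRs
    are computed under the six-covariate model (correct) and under the
    13-covariate model that adds noise covariates (overfitted).

    ``underfit``: outcomes come from the 13-covariate stand-in truth; SIRs
    are computed under the full model (correct) and under the
    six-covariate model that omits real risk factors (underfitted).

    Both SIR models are evaluated on the same simulated datasets, so the
    comparison is paired.
    """
    if arm not in ("overfit", "underfit"):
        raise ValueError("arm must be 'overfit' or 'underfit'")
    root = np.random.SeedSequence(spec.seed)
    ss_pool, ss_run = root.spawn(2)
    ext = replace(spec.generator, covariates=extended_covariates(), correlation=None)
    if arm == "overfit":
        # extras carry no effect on the outcome
        ext = replace(
            ext,
            covariates=tuple(
                replace(c, coefficient=0.0) if i >= 6 else c
                for i, c in enumerate(ext.covariates)
            ),
        )
    pool = CohortGenerator(ext).generate_cohort(seed=int(ss_pool.generate_state(1)[0] % 2**31))
    covs = pool.cohort.drop_outcomes()
    X_full = covs.covariates
    X_cms = X_full[:, :6]

    designs = {"overfit": [X_cms, X_full], "underfit": [X_full, X_cms]}[arm]
    res = simulate_classification_counts(
        X_full,
        covs.group_index,
        covs.n_hospitals,
        pool.params,
        spec.truth_replicates,
        ss_run,
        rank_designs=designs,
    )
    correct = res.estimates(0)
    mis = res.estimates(1)
    for tab in (correct, mis):
        tab.insert(0, "hospital_id", covs.hospital_ids)
        tab.insert(1, "volume", covs.volumes)
    return {"arm": arm, "correct": correct, "misspecified": mis, "pool": pool}


def run_application_report(cohort: CohortTable, spec: ScenarioSpec) -> dict:
    """End-to-end per-hospital accuracy report for an observed cohort.

    Fits the conditional and marginal models, runs Algorithm 1, computes
    the SIR table and worst-quartile flags, and reports minimum predicted
    events / volume to reach the conventional accuracy cutoffs (80% power,
    10% FPR, 80% PPV, 90% NPV)."""
    cond, loglik = fit_conditional(cohort)
    marg = fit_marginal(cohort)
    sirs = summarize_by_hospital(cohort, marg)
    flags = flag_upper_quartile(sirs["sir"].to_numpy())
    sim = QuartileAccuracySimulator(
        n_datasets=spec.n_datasets, random_state=spec.seed
    ).fit_cohort(cohort.drop_outcomes(), cond)
    tab = sim.results_.merge(
        sirs[["hospital_id", "observed_events", "predicted_events", "sir"]], on="hospital_id"
    )
    tab["worst_quartile_flag"] = flags

    thresholds = {}
    for x_name in ("predicted_events", "volume"):
        x = tab[x_name].to_numpy(dtype=float)
        thresholds[x_name] = {
            "power>=0.8": min_events_for_target(x, tab["power"], 0.8, ">="),
            "fpr<=0.1": min_events_for_target(x, tab["fpr"], 0.1, "<="),
            "ppv>=0.8": min_events_for_target(x, tab["ppv"], 0.8, ">="),
            "npv>=0.9": min_events_for_target(x, tab["npv"], 0.9, ">="),
        }
    return {
        "conditional": cond,
        "loglik": loglik,
        "marginal": marg,
        "table": tab,
        "n_flagged": int(flags.sum()),
        "n_not_flagged": int((~flags).sum()),
        "thresholds": thresholds,
    }


def write_report(out_dir, name: str, tables: dict, provenance: dict) -> None:
    """Write a scenario's DataFrames as CSV plus a JSON provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, val in tables.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{name}_{key}.csv", index=False)
    with open(out / f"{name}_provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
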