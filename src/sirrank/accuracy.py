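"""Monte-Carlo classification accuracy for worst-quartile ranking.

A hospital's true standing is its random intercept a_i; its observed
standing is its SIR.  Conditioning on the cohort's covariates and a set of
conditional-model parameters, the engine simulates K complete datasets
(fresh intercepts and outcomes each time), recomputes the SIRs, flags the
worst quartile of each statistic with a strict ">" at the 75th percentile,
and accumulates per-hospital true/false positive/negative counts.  From
those counts it estimates, per hospital,

    power = N_TP / (N_TP + N_FN),   FPR = N_FP / (N_FP + N_TN),
    PPV   = N_TP / (N_TP + N_FP),   NPV = N_TN / (N_TN + N_FN).

A 0/0 cell (e.g. PPV for a hospital never flagged) is reported as NaN,
never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .glmm import ConditionalParams, FitError, MarginalParams, attenuate, _irls

__all__ = [
    "SimulationConfig",
    "flag_upper_quartile",
    "simulate_dataset",
    "simulate_classification_counts",
    "QuartileAccuracySimulator",
    "run_algorithm1",
    "min_events_for_target",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the Monte-Carlo engine.

    ``marginal_source`` selects whether the SIR denominator model is refit
    on every simulated dataset ("refit") or supplied externally ("fixed",
    e.g. published national baseline coefficients).
    """

    n_datasets: int = 1000
    seed: int | None = None
    marginal_source: str = "refit"  # "refit" | "fixed"
    quantile_rule: str = "linear"
    exclusion_filter: bool = False
    min_predicted: float = 1.0

    def __post_init__(self):
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.marginal_source not in ("refit", "fixed"):
            raise ValueError("marginal_source must be 'refit' or 'fixed'")


def flag_upper_quartile(values, quantile_rule: str = "linear") -> np.ndarray:
    """True where a value strictly exceeds the pool's 75th percentile.

    With the default linear-interpolation quantile rule and 149 distinct
    values this flags exactly 37 hospitals.  If all values are equal no
    hospital strictly exceeds the threshold and none is flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to rank")
    q = np.percentile(v, 75, method=quantile_rule)
    flags = v > q
    if not flags.any():
        warnings.warn("no value strictly exceeds the 75th percentile", stacklevel=2)
    return flags


def simulate_dataset(X, group_index, n_groups, cond: ConditionalParams, rng):
    """One draw of hospital effects and outcomes given covariates.

    Returns ``(alpha_draws, outcomes)`` where alpha_i ~ N(alpha,
    sigma_alpha^2) i.i.d. and Y_ij ~ Bernoulli(expit(alpha_i + x'beta)).
    """
    X = np.asarray(X, dtype=float)
    gidx = np.asarray(group_index, dtype=np.intp)
    alpha_k = rng.normal(cond.alpha, cond.sigma_alpha, n_groups)
    p = expit(alpha_k[gidx] + X @ cond.beta)
    y = (rng.random(len(p)) < p).astype(np.int8)
    return alpha_k, y


@dataclass
class SimulationResult:
    """Counts and estimates from one engine run, one entry per SIR design."""

    counts: list  # list of (m, 4) arrays, columns n_tp, n_tn, n_fp, n_fn
    n_datasets: int
    n_redraws: int
    mean_predicted: list = field(default_factory=list)  # per design, (m,)
    true_flag_total: np.ndarray | None = None  # (m,), datasets with alpha flagged

    def estimates(self, design: int = 0) -> pd.DataFrame:
        tp, tn, fp, fn = self.counts[design].T

        def ratio(num, den):
            den = num + den
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
            return r

        return pd.DataFrame(
            {
                "n_tp": tp.astype(int),
                "n_tn": tn.astype(int),
                "n_fp": fp.astype(int),
                "n_fn": fn.astype(int),
                "power": ratio(tp, fn),
                "fpr": ratio(fp, tn),
                "ppv": ratio(tp, fp),
                "npv": ratio(tn, fn),
            }
        )


def simulate_classification_counts(
    X,
    group_index,
    n_groups: int,
    cond: ConditionalParams,
    n_datasets: int,
    seed_seq,
    *,
    rank_designs=None,
    marginal_source: str = "refit",
    fixed_marginal: MarginalParams | None = None,
    quantile_rule: str = "linear",
    include_mask=None,
    max_redraws: int = 100,
) -> SimulationResult:
    """Core Monte-Carlo loop shared by Algorithm 1, empirical-truth runs and
    the misspecification experiments.

    ``rank_designs`` is a list of covariate matrices used to compute SIRs
    (default: the truth covariates).  All designs are evaluated on the same
    simulated datasets, so paired comparisons between risk-adjustment models
    are free of extra Monte-Carlo noise.

    A dataset whose marginal refit fails (no events, or separation) is
    redrawn from a fresh child RNG stream; redraws are counted.  Results
    are reproducible from the seed sequence and independent of execution
    order because each dataset owns its own stream.
    """
    X = np.asarray(X, dtype=float)
    gidx = np.asarray(group_index, dtype=np.intp)
    m = int(n_groups)
    if rank_designs is None:
        rank_designs = [X]
    designs = [np.column_stack([np.ones(len(gidx)), np.asarray(D, dtype=float)]) for D in rank_designs]
    if marginal_source == "fixed":
        if fixed_marginal is None:
            raise ValueError("marginal_source='fixed' requires fixed_marginal")
        fixed_beta = [np.concatenate([[fixed_marginal.alpha_s], fixed_marginal.beta_s])]
        if len(designs) != 1:
            raise ValueError("fixed marginal parameters support a single design")

    include = np.ones(m, dtype=bool) if include_mask is None else np.asarray(include_mask, dtype=bool)
    if include.sum() < 2:
        raise ValueError("fewer than two hospitals remain after exclusion")

    eta_x = X @ cond.beta
    # warm starts per design: attenuated truth for the truth design, a
    # flat start elsewhere; updated sequentially (final MLEs do not depend
    # on the start, so order-invariance is preserved).
    approx = attenuate(cond)
    warm = []
    for D in designs:
        b = np.zeros(D.shape[1])
        b[0] = approx.alpha_s
        if D.shape[1] - 1 == len(approx.beta_s):
            b[1:] = approx.beta_s
        warm.append(b)

    counts = [np.zeros((m, 4), dtype=np.int64) for _ in designs]
    pred_sum = [np.zeros(m) for _ in designs]
    true_flag_total = np.zeros(m, dtype=np.int64)
    n_redraws = 0

    children = seed_seq.spawn(n_datasets)
    for k in range(n_datasets):
        stream = children[k]
        for attempt in range(max_redraws + 1):
            rng = np.random.default_rng(stream)
            alpha_k = rng.normal(cond.alpha, cond.sigma_alpha, m)
            p = expit(alpha_k[gidx] + eta_x)
            y = (rng.random(len(p)) < p).astype(float)
            try:
                if marginal_source == "refit":
                    betas = []
                    for d, D1 in enumerate(designs):
                        b = _irls(D1, y, start=warm[d])
                        warm[d] = b
                        betas.append(b)
                else:
                    betas = fixed_beta
            except FitError:
                n_redraws += 1
                stream = stream.spawn(1)[0]
                continue
            break
        else:
            raise FitError(f"dataset {k}: exceeded {max_redraws} redraws")

        yi = np.bincount(gidx, weights=y, minlength=m)
        true_flag = alpha_k[include] > np.percentile(alpha_k[include], 75, method=quantile_rule)
        tf_full = np.zeros(m, dtype=bool)
        tf_full[include] = true_flag
        true_flag_total += tf_full & include

        for d, (D1, b) in enumerate(zip(designs, betas)):
            pred = np.bincount(gidx, weights=expit(D1 @ b), minlength=m)
            pred_sum[d] += pred
            sir = yi[include] / pred[include]
            sir_flag = sir > np.percentile(sir, 75, method=quantile_rule)
            sf_full = np.zeros(m, dtype=bool)
            sf_full[include] = sir_flag
            tp = tf_full & sf_full
            tn = ~tf_full & ~sf_full & include
            fp = ~tf_full & sf_full
            fn = tf_full & ~sf_full
            counts[d][:, 0] += tp
            counts[d][:, 1] += tn
            counts[d][:, 2] += fp
            counts[d][:, 3] += fn

    return SimulationResult(
        counts=counts,
        n_datasets=n_datasets,
        n_redraws=n_redraws,
        mean_predicted=[s / n_datasets for s in pred_sum],
        true_flag_total=true_flag_total,
    )


class QuartileAccuracySimulator(BaseEstimator):
    """Algorithm-1 estimator of per-hospital worst-quartile accuracy.

    Given a cohort's covariates and conditional-model parameters (usually
    estimated from the observed data by :class:`~sirrank.glmm.RandomInterceptLogit`),
    ``fit`` runs the Monte-Carlo engine and exposes per-hospital counts and
    Power/FPR/PPV/NPV estimates as fitted attributes.

    Parameters
    ----------
    n_datasets : int, default 1000
        Number of simulated datasets K.
    random_state : int or None
        Master seed; one child stream is spawned per dataset.
    marginal_source : {"refit", "fixed"}
        Refit the SIR denominator model per dataset, or use
        externally supplied (e.g. published) marginal parameters.
    quantile_rule : str
        Quantile interpolation rule for the 75th percentile.
    exclude_below_predicted : float or None
        If set, hospitals whose predicted events under the attenuated
        input model fall below this threshold are excluded from ranking
        (CDC-style filter); their metrics are NaN.

    Attributes
    ----------
    counts_ : DataFrame with n_tp, n_tn, n_fp, n_fn per hospital.
    results_ : DataFrame with counts, metrics, volume and mean predicted
        events across the K datasets.
    power_, fpr_, ppv_, npv_ : ndarray per-hospital estimates (NaN = 0/0).
    n_redraws_ : int, datasets redrawn because a marginal refit failed.
    """

    def __init__(
        self,
        n_datasets: int = 1000,
        random_state: int | None = None,
        marginal_source: str = "refit",
        fixed_marginal: MarginalParams | None = None,
        quantile_rule: str = "linear",
        exclude_below_predicted: float | None = None,
    ):
        self.n_datasets = n_datasets
        self.random_state = random_state
        self.marginal_source = marginal_source
        self.fixed_marginal = fixed_marginal
        self.quantile_rule = quantile_rule
        self.exclude_below_predicted = exclude_below_predicted

    def fit(self, X, groups, conditional: ConditionalParams, hospital_ids=None, y=None):
        X = np.asarray(X, dtype=float)
        labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
        gidx = gidx.astype(np.intp)
        m = len(labels)
        if m < 2:
            raise ValueError("need at least two hospitals")

        include = None
        if self.exclude_below_predicted is not None:
            approx = attenuate(conditional)
            p0 = expit(approx.alpha_s + X @ approx.beta_s)
            pred0 = np.bincount(gidx, weights=p0, minlength=m)
            include = pred0 >= self.exclude_below_predicted

        seed_seq = np.random.SeedSequence(self.random_state)
        res = simulate_classification_counts(
            X,
            gidx,
            m,
            conditional,
            self.n_datasets,
            seed_seq,
            marginal_source=self.marginal_source,
            fixed_marginal=self.fixed_marginal,
            quantile_rule=self.quantile_rule,
            include_mask=include,
        )
        est = res.estimates(0)
        est.insert(0, "hospital_id", hospital_ids if hospital_ids is not None else labels)
        est.insert(1, "volume", np.bincount(gidx, minlength=m))
        est.insert(2, "mean_predicted_events", res.mean_predicted[0])
        if include is not None:
            est.loc[~include, ["power", "fpr", "ppv", "npv"]] = np.nan
            est["excluded"] = ~include
        self.results_ = est
        self.counts_ = est[["n_tp", "n_tn", "n_fp", "n_fn"]]
        self.power_ = est["power"].to_numpy()
        self.fpr_ = est["fpr"].to_numpy()
        self.ppv_ = est["ppv"].to_numpy()
        self.npv_ = est["npv"].to_numpy()
        self.n_redraws_ = res.n_redraws
        self.include_mask_ = include
        return self

    def fit_cohort(self, cohort, conditional: ConditionalParams):
        """Convenience wrapper taking a :class:`~sirrank.cohort.CohortTable`."""
        return self.fit(
            cohort.covariates,
            cohort.frame[cohort.schema.hospital_col].to_numpy(),
            conditional,
        )


def run_algorithm1(
    covariates_cohort,
    cond: ConditionalParams,
    config: SimulationConfig = SimulationConfig(),
    fixed_marginal: MarginalParams | None = None,
):
    """Functional wrapper around :class:`QuartileAccuracySimulator`.

    Returns ``(counts, estimates)`` DataFrames, one row per hospital.
    """
    sim = QuartileAccuracySimulator(
        n_datasets=config.n_datasets,
        random_state=config.seed,
        marginal_source=config.marginal_source,
        fixed_marginal=fixed_marginal,
        quantile_rule=config.quantile_rule,
        exclude_below_predicted=config.min_predicted if config.exclusion_filter else None,
    )
    sim.fit_cohort(covariates_cohort, cond)
    return sim.counts_, sim.results_


def min_events_for_target(x_values, metric_values, target: float, direction: str = ">="):
    """Smallest x (predicted events or volume) above which every hospital
    meets an accuracy criterion.

    Scans the empirical frontier: returns the smallest v among the supplied
    x-values such that *every* hospital with x >= v satisfies
    ``metric direction target``; ``None`` if even the largest-x hospitals
    fail.  Hospitals with undefined (NaN) metrics are ignored.
    """
    if direction not in (">=", "<="):
        raise ValueError("direction must be '>=' or '<='")
    x = np.asarray(x_values, dtype=float)
    v = np.asarray(metric_values, dtype=float)
    if x.size == 0 or x.size != v.size:
        raise ValueError("need matching nonempty x and metric vectors")
    keep = ~np.isnan(v)
    x, v = x[keep], v[keep]
    if x.size == 0:
        return None
    ok = v >= target if direction == ">=" else v <= target
    order = np.argsort(-x, kind="stable")  # descending x
    best = None
    i = 0
    n = len(x)
    while i < n:
        # process ties in x as one block: all must pass
        j = i
        block_ok = True
        while j < n and x[order[j]] == x[order[i]]:
            block_ok &= bool(ok[order[j]])
            j += 1
        if not block_ok:
            break
        best = float(x[order[i]])
        i = j
    return best
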