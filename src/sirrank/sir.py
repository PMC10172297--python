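"""Standardized infection ratio (SIR).

SIR_i = Y_i / pi_hat_i: the observed number of infections at a hospital
divided by the number the population-averaged (marginal) risk model
predicts for the same patients at a "typical" hospital.  SIR > 1 reads
"worse than average", SIR < 1 "better than average".
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["predicted_events", "predicted_events_by_group", "compute_sir", "sir_table"]


def predicted_events(X: np.ndarray, marginal) -> float:
    """Predicted event count for one hospital's covariate rows.

    Sum over rows of expit(alpha_s + x' beta_s); lies in [0, n_i].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(marginal.beta_s, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"{X.shape[1]} covariates vs {beta.shape[0]} coefficients")
    return float(expit(marginal.alpha_s + X @ beta).sum())


def predicted_events_by_group(X, group_index, n_groups: int, marginal) -> np.ndarray:
    """Vector of predicted events per hospital for a whole cohort."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(marginal.beta_s, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"{X.shape[1]} covariates vs {beta.shape[0]} coefficients")
    p = expit(marginal.alpha_s + X @ beta)
    return np.bincount(group_index, weights=p, minlength=n_groups)


def compute_sir(observed: float, predicted: float) -> float:
    """Observed / predicted events; undefined when predicted is zero."""
    if observed < 0 or predicted < 0:
        raise ValueError("negative event counts")
    if predicted == 0:
        raise ZeroDivisionError(
            "SIR undefined: zero predicted events"
            + (" with nonzero observed events" if observed > 0 else "")
        )
    return float(observed) / float(predicted)


def sir_table(cohort, marginal, *, min_predicted: float | None = None):
    """Per-hospital SIR report, optionally applying the CDC-style filter
    that excludes hospitals with fewer than ``min_predicted`` (typically 1)
    predicted events from ranking."""
    from .cohort import summarize_by_hospital

    tab = summarize_by_hospital(cohort, marginal)
    if min_predicted is not None:
        tab = tab[tab["predicted_events"] >= min_predicted].reset_index(drop=True)
    return tab
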