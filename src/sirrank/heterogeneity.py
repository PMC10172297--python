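"""Pool-level reliability summaries.

Two closed-form quantities describe how rankable a pool of hospitals is:

* the expected empirical variance of hospital-level event rates,
  E(s^2) = pi (1 - pi) / n_H + sigma_alpha^2, where pi is the overall event
  rate, n_H the harmonic mean volume and sigma_alpha^2 the between-hospital
  variance of true rates; and
* the rankability index r = sigma_alpha^2 / (sigma_alpha^2 + median(s_i^2)),
  the fraction of observed between-hospital variation attributable to true
  differences rather than sampling noise.

The per-hospital sampling variance s_i^2 of an observed rate p_hat_i is
estimated as p_hat_i (1 - p_hat_i) / n_i; hospitals with zero or all events
use a half-event continuity correction, p_hat_i = (Y_i + 0.5) / (n_i + 1),
so the estimate is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "harmonic_mean",
    "expected_empirical_variance",
    "rankability",
    "sampling_variances",
    "HeterogeneitySummary",
    "summarize_pool",
]


def harmonic_mean(volumes) -> float:
    """m / sum(1/n_i) for strictly positive volumes."""
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume vector")
    if np.any(v <= 0):
        raise ValueError("volumes must be strictly positive")
    return float(v.size / np.sum(1.0 / v))


def expected_empirical_variance(
    pi: float, harmonic_mean_volume: float, sigma_alpha_sq: float
) -> float:
    """E(s^2) = pi(1-pi)/n_H + sigma_alpha^2."""
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must be in (0, 1)")
    if harmonic_mean_volume <= 0:
        raise ValueError("harmonic mean volume must be positive")
    if sigma_alpha_sq < 0:
        raise ValueError("sigma_alpha_sq must be nonnegative")
    return pi * (1.0 - pi) / harmonic_mean_volume + sigma_alpha_sq


def rankability(sigma_alpha_sq: float, median_sampling_var: float) -> float:
    """r = sigma_alpha^2 / (sigma_alpha^2 + median(s_i^2)), in [0, 1]."""
    if sigma_alpha_sq < 0 or median_sampling_var < 0:
        raise ValueError("variance components must be nonnegative")
    if sigma_alpha_sq == 0 and median_sampling_var == 0:
        raise ValueError("rankability undefined when both variances are zero")
    return sigma_alpha_sq / (sigma_alpha_sq + median_sampling_var)


def sampling_variances(observed_events, volumes, scale: str = "rate") -> np.ndarray:
    """Per-hospital sampling variance of the observed event rate.

    ``scale="rate"``: s_i^2 = p_hat_i (1 - p_hat_i) / n_i with the
    half-event correction at 0/n_i.  ``scale="logit"``: the delta-method
    variance of logit(p_hat_i), 1/(Y_i + 0.5) + 1/(n_i - Y_i + 0.5) — the
    scale on which the GLMM's between-hospital variance lives, hence the
    natural pairing for the rankability index.
    """
    y = np.asarray(observed_events, dtype=float)
    n = np.asarray(volumes, dtype=float)
    if np.any(n <= 0):
        raise ValueError("volumes must be strictly positive")
    if np.any((y < 0) | (y > n)):
        raise ValueError("observed events must lie in [0, volume]")
    if scale == "rate":
        p = y / n
        boundary = (y == 0) | (y == n)
        p = np.where(boundary, (y + 0.5) / (n + 1.0), p)
        return p * (1.0 - p) / n
    if scale == "logit":
        return 1.0 / (y + 0.5) + 1.0 / (n - y + 0.5)
    raise ValueError("scale must be 'rate' or 'logit'")


@dataclass(frozen=True)
class HeterogeneitySummary:
    overall_rate: float
    harmonic_mean_volume: float
    sigma_alpha_sq: float
    expected_s2: float
    median_sampling_var: float
    rankability: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_pool(
    observed_events, volumes, sigma_alpha_sq: float, scale: str = "rate"
) -> HeterogeneitySummary:
    """Pool-level reliability report from per-hospital counts and volumes.

    ``sigma_alpha_sq`` must live on the same scale as the sampling
    variances: pass the between-hospital variance of true *rates* with the
    default ``scale="rate"`` (the pairing of the closed-form E(s^2)), or
    the logit-scale GLMM variance with ``scale="logit"`` (the natural
    pairing for rankability).
    """
    y = np.asarray(observed_events, dtype=float)
    n = np.asarray(volumes, dtype=float)
    pi = float(y.sum() / n.sum())
    n_h = harmonic_mean(n)
    s2 = sampling_variances(y, n, scale=scale)
    med = float(np.median(s2))
    return HeterogeneitySummary(
        overall_rate=pi,
        harmonic_mean_volume=n_h,
        sigma_alpha_sq=float(sigma_alpha_sq),
        expected_s2=expected_empirical_variance(pi, n_h, sigma_alpha_sq),
        median_sampling_var=med,
        rankability=rankability(sigma_alpha_sq, med),
    )
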