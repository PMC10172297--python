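"""Synthetic multi-hospital colon-surgery cohorts.

The real colon-surgery SSI data behind the motivating application are not
publicly available, so this module generates cohorts that emulate their
published structure: 149 hospitals with volumes between 2 and 903 (about
39,500 patients in total), six risk-adjustment covariates with the
published coefficients and intraclass correlations, pairwise covariate
correlations within the published range, a hospital random intercept with
standard deviation 0.5, and an overall infection rate near 3.1%.

Covariates are produced by a latent-Gaussian factor construction: each
covariate's latent score is a hospital-level component (variance = target
ICC) plus a patient-level component (variance = 1 - ICC), with the same
correlation matrix applied at both levels so the total latent correlation
is close to the specified one.  Continuous covariates are affine
transforms of the latent score, binaries are thresholded at the normal
quantile of the target prevalence, and ordinal scores are cut at the
quantiles of the category probabilities.  ICC targets therefore hold on
the latent scale; thresholding attenuates the observed-scale ICC of
binary covariates, which the tests bound by simulation.

Covariate marginal distributions (age mean/SD, binary prevalences, ASA
category probabilities) are NOT published for the motivating data; the
defaults here are plausible values for a U.S. colon-surgery population and
are config-overridable.  The same applies to the volume distribution shape
(a discretized truncated log-normal calibrated to range 2-903 and mean
265) and to the seven extra "claims-plus-EHR"-style covariates used by the
underfitting experiment, whose coefficients are synthetic stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, roots_hermite

from .cohort import CohortSchema, CohortTable
from .glmm import ConditionalParams

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "CohortGenerator",
    "SyntheticCohort",
    "default_covariates",
    "extended_covariates",
    "default_correlation",
    "resample_within_hospital",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: marginal type and parameters, coefficient, target ICC."""

    name: str
    kind: str  # "continuous" | "binary" | "ordinal"
    coefficient: float
    icc: float
    mean: float = 0.0  # continuous only
    sd: float = 1.0  # continuous only
    prevalence: float = 0.5  # binary only
    levels: tuple = ()  # ordinal: values
    probs: tuple = ()  # ordinal: category probabilities

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("ICC must be in [0, 1)")


def default_covariates() -> tuple[CovariateSpec, ...]:
    """The six CMS-style risk factors with published coefficients and ICCs.

    Marginal distribution parameters (means, prevalences, ASA category
    probabilities) are synthetic defaults, not published values.
    """
    return (
        CovariateSpec("age", "continuous", -0.0087, 0.0732, mean=62.0, sd=13.0),
        CovariateSpec("gender_male", "binary", 0.0361, 0.0229, prevalence=0.5),
        CovariateSpec(
            "asa_score", "ordinal", 0.1470, 0.1123,
            levels=(1, 2, 3, 4, 5), probs=(0.04, 0.24, 0.47, 0.21, 0.04),
        ),
        CovariateSpec("diabetes", "binary", 0.1181, 0.0230, prevalence=0.20),
        CovariateSpec("bmi_ge30", "binary", 0.4235, 0.0166, prevalence=0.35),
        CovariateSpec("closure_other", "binary", -0.9813, 0.0433, prevalence=0.05),
    )


def extended_covariates() -> tuple[CovariateSpec, ...]:
    """Six CMS-style factors plus seven synthetic claims/EHR-style factors.

    The extras (laparoscopy, procedure duration, wound class, comorbidity
    burden, concomitant procedures, anesthesia) mimic the richer
    risk-adjustment model of the underfitting experiment; their
    coefficients are synthetic stand-ins of realistic magnitude, since the
    richer model's fitted values are not published.
    """
    extras = (
        CovariateSpec("laparoscopy", "binary", -0.5200, 0.1500, prevalence=0.45),
        CovariateSpec("duration_hours", "continuous", 0.3000, 0.0800, mean=2.5, sd=1.0),
        CovariateSpec(
            "wound_class", "ordinal", 0.2500, 0.0600,
            levels=(1, 2, 3, 4), probs=(0.10, 0.60, 0.20, 0.10),
        ),
        CovariateSpec("comorbidity_count", "continuous", 0.1200, 0.0500, mean=2.0, sd=1.5),
        CovariateSpec("concomitant_colon", "binary", 0.2800, 0.0300, prevalence=0.15),
        CovariateSpec("concomitant_noncolon", "binary", 0.3500, 0.0400, prevalence=0.10),
        CovariateSpec("general_anesthesia", "binary", 0.2000, 0.0500, prevalence=0.90),
    )
    return default_covariates() + extras


def default_correlation(n: int = 6) -> np.ndarray:
    """Latent correlation among the covariates.

    Entries are synthetic but kept inside the published range of pairwise
    covariate correlations [-0.2722, 0.6515] for the motivating data.  For
    the 13-covariate extended set, the extras correlate modestly with ASA
    score and with each other where clinically plausible.
    """
    base = np.array(
        [
            #  age   male   asa    diab   bmi    clos
            [1.00, -0.05, 0.40, 0.25, -0.10, 0.05],
            [-0.05, 1.00, 0.05, 0.05, 0.05, 0.00],
            [0.40, 0.05, 1.00, 0.30, 0.25, 0.10],
            [0.25, 0.05, 0.30, 1.00, 0.35, 0.05],
            [-0.10, 0.05, 0.25, 0.35, 1.00, 0.00],
            [0.05, 0.00, 0.10, 0.05, 0.00, 1.00],
        ]
    )
    if n == 6:
        return base
    if n == 13:
        R = np.eye(13)
        R[:6, :6] = base
        # extras: laparoscopy, duration, wound, comorb, conc_colon,
        # conc_noncolon, anesthesia (indices 6..12)
        pairs = {
            (2, 6): -0.15,  # asa ~ laparoscopy
            (2, 7): 0.20,  # asa ~ duration
            (2, 9): 0.25,  # asa ~ comorbidity
            (0, 9): 0.35,  # age ~ comorbidity
            (3, 9): 0.30,  # diabetes ~ comorbidity
            (6, 7): -0.25,  # laparoscopy ~ duration
            (7, 10): 0.20,  # duration ~ concomitant colon
            (7, 11): 0.20,  # duration ~ concomitant noncolon
            (8, 7): 0.15,  # wound class ~ duration
        }
        for (i, j), r in pairs.items():
            R[i, j] = R[j, i] = r
        return R
    raise ValueError("default correlation defined for 6 or 13 covariates")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic pool.

    The intercept handling mirrors how the published parameters arose: the
    random-intercept mean was fitted to an unpublished covariate
    distribution, so reusing it verbatim with synthetic covariates would
    not reproduce the published 3.1% overall rate.  When ``target_rate``
    is set (the default), the intercept is recalibrated by root finding so
    the marginal event rate over the generated pool hits the target;
    setting ``target_rate=None`` uses ``alpha`` as-is.
    """

    m: int = 149
    volume_min: int = 2
    volume_max: int = 903
    volume_mean: float = 265.0
    volume_log_sd: float = 1.0
    anchor_volumes: tuple[int, ...] = (78, 303)
    covariates: tuple[CovariateSpec, ...] = field(default_factory=default_covariates)
    correlation: np.ndarray | None = None
    alpha: float = -2.7862
    sigma_alpha: float = 0.5
    target_rate: float | None = 0.031
    seed: int | None = None

    def corr(self) -> np.ndarray:
        R = self.correlation if self.correlation is not None else default_correlation(len(self.covariates))
        R = np.asarray(R, dtype=float)
        if R.shape != (len(self.covariates),) * 2:
            raise ValueError("correlation shape does not match covariate count")
        if np.min(np.linalg.eigvalsh(R)) <= 1e-10:
            raise ValueError("correlation matrix is not positive definite")
        return R

    @property
    def beta(self) -> np.ndarray:
        return np.array([c.coefficient for c in self.covariates])

    @property
    def schema(self) -> CohortSchema:
        return CohortSchema(
            "hospital_id", "outcome", tuple(c.name for c in self.covariates)
        )


@dataclass
class SyntheticCohort:
    """A generated cohort together with its ground truth."""

    cohort: CohortTable
    params: ConditionalParams  # the generating (possibly recalibrated) truth
    hospital_effects: np.ndarray  # realized alpha_i


class CohortGenerator:
    """Draws complete synthetic cohorts from a :class:`GeneratorConfig`."""

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config or GeneratorConfig()
        self.config.corr()  # validate eagerly

    # -- volumes ------------------------------------------------------------

    def _volume_mu(self) -> float:
        """Log-normal location such that the truncated mean hits the target."""
        cfg = self.config
        s = cfg.volume_log_sd
        lo, hi = cfg.volume_min, cfg.volume_max

        def trunc_mean(mu):
            a = (np.log(lo) - mu) / s
            b = (np.log(hi) - mu) / s
            za, zb = stats.norm.cdf(a), stats.norm.cdf(b)
            # E[X | lo<=X<=hi] for lognormal(mu, s)
            num = stats.norm.cdf(b - s) - stats.norm.cdf(a - s)
            return np.exp(mu + 0.5 * s**2) * num / (zb - za)

        if not cfg.volume_min < cfg.volume_mean < cfg.volume_max:
            raise ValueError("volume_mean must lie strictly inside the bounds")
        # truncated mean is monotone in mu with limits (volume_min, volume_max)
        mu_lo = np.log(lo) - 8.0 * s
        mu_hi = np.log(hi) + 8.0 * s
        return brentq(lambda mu: trunc_mean(mu) - cfg.volume_mean, mu_lo, mu_hi)

    def generate_volumes(self, rng) -> np.ndarray:
        """m integer volumes in [min, max] from a discretized truncated
        log-normal, with any configured anchor volumes inserted verbatim."""
        cfg = self.config
        if any(not cfg.volume_min <= a <= cfg.volume_max for a in cfg.anchor_volumes):
            raise ValueError("anchor volumes outside the configured bounds")
        n_free = cfg.m - len(cfg.anchor_volumes)
        if n_free < 0:
            raise ValueError("more anchor volumes than hospitals")
        if cfg.volume_min == cfg.volume_max:  # degenerate: constant volumes
            return np.full(cfg.m, cfg.volume_min, dtype=int)
        mu = self._volume_mu()
        out = np.empty(0, dtype=int)
        while len(out) < n_free:  # rejection sampling into the bounds
            draw = np.exp(rng.normal(mu, cfg.volume_log_sd, 2 * (n_free - len(out)) + 8))
            v = np.rint(draw).astype(int)
            out = np.concatenate([out, v[(v >= cfg.volume_min) & (v <= cfg.volume_max)]])
        vols = np.concatenate([np.asarray(cfg.anchor_volumes, dtype=int), out[:n_free]])
        return vols

    # -- covariates ---------------------------------------------------------

    def generate_covariates(self, volumes, rng) -> CohortTable:
        """Correlated covariates with hospital-level components sized to the
        target ICCs on the latent scale.  Returns a covariates-only cohort
        (hospital ids H001..Hm, no outcome column)."""
        cfg = self.config
        volumes = np.asarray(volumes, dtype=int)
        m = len(volumes)
        N = int(volumes.sum())
        gidx = np.repeat(np.arange(m), volumes)
        specs = cfg.covariates
        p = len(specs)
        R = cfg.corr()
        L = np.linalg.cholesky(R)
        icc = np.array([c.icc for c in specs])

        B = rng.standard_normal((m, p)) @ L.T  # hospital-level components
        E = rng.standard_normal((N, p)) @ L.T  # patient-level components
        latent = np.sqrt(icc) * B[gidx] + np.sqrt(1.0 - icc) * E
        # kept for calibration checks (latent-scale ICC / correlation)
        self.last_latent_ = latent
        self.last_group_index_ = gidx

        cols = {}
        width = max(3, len(str(m)))
        ids = np.array([f"H{i + 1:0{width}d}" for i in range(m)])
        cols["hospital_id"] = ids[gidx]
        for j, spec in enumerate(specs):
            z = latent[:, j]
            if spec.kind == "continuous":
                cols[spec.name] = spec.mean + spec.sd * z
            elif spec.kind == "binary":
                cols[spec.name] = (z > stats.norm.ppf(1.0 - spec.prevalence)).astype(int)
            else:  # ordinal
                cuts = stats.norm.ppf(np.cumsum(spec.probs)[:-1])
                cols[spec.name] = np.asarray(spec.levels)[np.searchsorted(cuts, z)]
        import pandas as pd

        frame = pd.DataFrame(cols)
        schema = CohortSchema("hospital_id", None, tuple(c.name for c in specs))
        return CohortTable(frame, schema)

    # -- intercept calibration ---------------------------------------------

    def calibrate_intercept(
        self, covariates: CohortTable, target_rate: float, sigma_alpha: float | None = None
    ) -> float:
        """Intercept alpha at which the pool's marginal event rate equals
        ``target_rate``.

        The marginal rate E[expit(alpha + sigma Z + x'beta)] is evaluated by
        Gauss-Hermite quadrature over the random effect and averaging over
        the supplied covariate rows; the root is found by Brent's method to
        well within 1e-3 on the rate scale.
        """
        if not 0.0 < target_rate < 1.0:
            raise ValueError("target_rate must be in (0, 1)")
        cfg = self.config
        sigma = cfg.sigma_alpha if sigma_alpha is None else sigma_alpha
        eta_x = covariates.covariates @ cfg.beta
        z, w = roots_hermite(30)
        w = w / np.sqrt(np.pi)

        def rate(a):
            acc = 0.0
            for zq, wq in zip(z, w):
                acc += wq * np.mean(expit(a + np.sqrt(2.0) * sigma * zq + eta_x))
            return acc

        lo, hi = -20.0, 10.0
        if not (rate(lo) < target_rate < rate(hi)):
            raise ValueError("target rate not bracketed by the search range")
        return float(brentq(lambda a: rate(a) - target_rate, lo, hi, xtol=1e-8))

    # -- outcomes -----------------------------------------------------------

    def generate_outcomes(self, covariates: CohortTable, params: ConditionalParams, rng):
        """Hospital effects and Bernoulli outcomes given covariates."""
        from .accuracy import simulate_dataset

        return simulate_dataset(
            covariates.covariates, covariates.group_index, covariates.n_hospitals, params, rng
        )

    def generate_cohort(self, seed: int | None = None) -> SyntheticCohort:
        """Full pipeline: volumes -> covariates -> intercept calibration ->
        hospital effects and outcomes.  Reproducible from the seed."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        volumes = self.generate_volumes(rng)
        covs = self.generate_covariates(volumes, rng)
        alpha = cfg.alpha
        if cfg.target_rate is not None:
            alpha = self.calibrate_intercept(covs, cfg.target_rate)
        params = ConditionalParams(alpha=alpha, beta=cfg.beta, sigma_alpha_sq=cfg.sigma_alpha**2)
        effects, y = self.generate_outcomes(covs, params, rng)
        return SyntheticCohort(covs.with_outcomes(y), params, effects)


def resample_within_hospital(cohort: CohortTable, rng) -> CohortTable:
    """Resample each hospital's rows with replacement from its own rows.

    Volumes are preserved exactly; the outcome column is dropped because
    outcomes are regenerated after resampling.  Used by the event-rate and
    variance sweeps to vary model parameters while preserving each
    hospital's case-mix distribution.
    """
    base = cohort.drop_outcomes() if cohort.schema.outcome_col is not None else cohort
    gidx = base.group_index
    n = len(gidx)
    take = np.empty(n, dtype=np.intp)
    for i in range(base.n_hospitals):
        rows = np.nonzero(gidx == i)[0]
        take[rows] = rng.choice(rows, size=len(rows), replace=True)
    frame = base.frame.iloc[take].reset_index(drop=True)
    return CohortTable(frame, base.schema)


def truth_for(config: GeneratorConfig, covariates: CohortTable) -> ConditionalParams:
    """Generating parameters for a covariate pool under a config (with the
    intercept recalibrated if the config targets an overall rate)."""
    gen = CohortGenerator(config)
    alpha = config.alpha
    if config.target_rate is not None:
        alpha = gen.calibrate_intercept(covariates, config.target_rate)
    return ConditionalParams(alpha, config.beta, config.sigma_alpha**2)
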