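"""Patient-level cohort container and per-hospital summaries.

A cohort is a flat table of surgical episodes: one row per patient with a
hospital identifier, a binary outcome (e.g. deep-incisional / organ-space
surgical site infection) and a fixed set of numeric risk-adjustment
covariates.  Hospitals are opaque string labels; covariates are plain
floats (ordinal scores such as ASA class enter as numeric values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSchema",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "summarize_by_hospital",
]


class CohortValidationError(ValueError):
    """Raised when a table violates the cohort contract."""


@dataclass(frozen=True)
class CohortSchema:
    """Column-name map for a cohort CSV.

    Parameters
    ----------
    hospital_col : name of the hospital identifier column.
    outcome_col : name of the binary outcome column, or ``None`` for a
        covariates-only table (e.g. after within-hospital resampling,
        before outcomes are regenerated).
    covariate_cols : ordered covariate column names.
    """

    hospital_col: str = "hospital_id"
    outcome_col: str | None = "outcome"
    covariate_cols: tuple[str, ...] = ()


@dataclass
class CohortTable:
    """Validated patient-level cohort.

    Wraps a :class:`pandas.DataFrame` whose rows are patients.  Exposes the
    quantities every downstream module needs: the number of hospitals ``m``,
    per-hospital volumes ``n_i``, the total size ``N``, the covariate matrix
    and integer hospital codes.
    """

    frame: pd.DataFrame
    schema: CohortSchema = field(default_factory=CohortSchema)

    def __post_init__(self) -> None:
        df = self.frame
        sch = self.schema
        needed = [sch.hospital_col, *sch.covariate_cols]
        if sch.outcome_col is not None:
            needed.insert(1, sch.outcome_col)
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {missing}")
        if df[sch.hospital_col].isna().any():
            bad = df.index[df[sch.hospital_col].isna()].tolist()
            raise CohortValidationError(f"missing hospital_id in rows {bad[:10]}")
        if sch.outcome_col is not None:
            y = df[sch.outcome_col]
            bad_mask = ~y.isin([0, 1]) | y.isna()
            if bad_mask.any():
                bad = df.index[bad_mask].tolist()
                raise CohortValidationError(
                    f"outcome values outside {{0,1}} in rows {bad[:10]}"
                )
        for c in sch.covariate_cols:
            if df[c].isna().any():
                bad = df.index[df[c].isna()].tolist()
                raise CohortValidationError(
                    f"missing values in covariate {c!r}, rows {bad[:10]}"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    @property
    def hospital_ids(self) -> np.ndarray:
        """Distinct hospital labels in first-appearance order."""
        return pd.unique(self.frame[self.schema.hospital_col].to_numpy())

    @property
    def n_hospitals(self) -> int:
        return len(self.hospital_ids)

    @property
    def group_index(self) -> np.ndarray:
        """Integer hospital code per row, 0..m-1 in first-appearance order."""
        ids = self.frame[self.schema.hospital_col]
        codes = pd.Categorical(ids, categories=self.hospital_ids).codes
        return np.asarray(codes, dtype=np.intp)

    @property
    def volumes(self) -> np.ndarray:
        """n_i per hospital, aligned with :attr:`hospital_ids`."""
        return np.bincount(self.group_index, minlength=self.n_hospitals)

    @property
    def covariates(self) -> np.ndarray:
        """N x p float matrix in schema column order."""
        return self.frame[list(self.schema.covariate_cols)].to_numpy(dtype=float)

    @property
    def outcomes(self) -> np.ndarray:
        if self.schema.outcome_col is None:
            raise CohortValidationError("cohort has no outcome column")
        return self.frame[self.schema.outcome_col].to_numpy(dtype=int)

    def drop_outcomes(self) -> "CohortTable":
        """Covariates-only copy (outcomes to be regenerated downstream)."""
        sch = self.schema
        keep = [sch.hospital_col, *sch.covariate_cols]
        new_schema = CohortSchema(sch.hospital_col, None, sch.covariate_cols)
        return CohortTable(self.frame[keep].copy(), new_schema)

    def with_outcomes(self, y: np.ndarray) -> "CohortTable":
        """Copy with a (re)generated outcome column."""
        sch = self.schema
        out_col = sch.outcome_col or "outcome"
        df = self.frame.copy()
        df[out_col] = np.asarray(y, dtype=int)
        cols = [sch.hospital_col, out_col, *sch.covariate_cols]
        return CohortTable(df[cols], CohortSchema(sch.hospital_col, out_col, sch.covariate_cols))


def read_cohort(path, schema: CohortSchema) -> CohortTable:
    """Read and validate a cohort CSV (comma-separated, header row, UTF-8)."""
    df = pd.read_csv(path, dtype={schema.hospital_col: str})
    return CohortTable(df, schema)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV so that :func:`read_cohort` round-trips it."""
    cohort.frame.to_csv(path, index=False)


def summarize_by_hospital(cohort: CohortTable, marginal) -> pd.DataFrame:
    """Per-hospital volume, observed events, predicted events and SIR.

    ``marginal`` is a :class:`sirrank.glmm.MarginalParams`; predicted events
    for hospital i are the sum of population-averaged infection
    probabilities expit(alpha_s + x'beta_s) over its patients, and the SIR
    is observed / predicted.  Hospitals with zero predicted events and zero
    observed events get an undefined (NaN) SIR and a warning; zero predicted
    with nonzero observed is an error.
    """
    from .sir import compute_sir, predicted_events_by_group

    X = cohort.covariates
    if X.shape[1] != len(marginal.beta_s):
        raise ValueError(
            f"marginal has {len(marginal.beta_s)} coefficients for "
            f"{X.shape[1]} covariate columns"
        )
    g = cohort.group_index
    m = cohort.n_hospitals
    pred = predicted_events_by_group(X, g, m, marginal)
    obs = np.bincount(g, weights=cohort.outcomes, minlength=m)
    sirs = np.full(m, np.nan)
    for i in range(m):
        if pred[i] == 0 and obs[i] == 0:
            warnings.warn(
                f"hospital {cohort.hospital_ids[i]!r} has zero predicted and "
                "observed events; SIR undefined, excluded from ranking",
                stacklevel=2,
            )
            continue
        sirs[i] = compute_sir(obs[i], pred[i])
    return pd.DataFrame(
        {
            "hospital_id": cohort.hospital_ids,
            "volume": cohort.volumes,
            "observed_events": obs.astype(int),
            "predicted_events": pred,
            "sir": sirs,
        }
    )
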