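"""Distant-metastasis-free survival evaluation of the tumour subtypes.

Thin, typed wrappers around lifelines: Kaplan-Meier product-limit curves,
the log-rank test for group differences, and Cox proportional-hazards
regression with Efron tie handling.  Time is measured in months; the
clinical endpoint of interest is DMFS at 5 years (60 months).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

__all__ = [
    "SurvivalData",
    "KmCurve",
    "km_estimate",
    "logrank",
    "cox_fit",
    "survival_at_5y",
    "FIVE_YEARS_MONTHS",
]

FIVE_YEARS_MONTHS = 60.0


@dataclass
class SurvivalData:
    """Follow-up times (months), event flags and optional covariates."""

    time: pd.Series
    event: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = pd.Series(self.time, dtype=float)
        self.event = pd.Series(self.event).astype(int).reindex(self.time.index)
        if not np.isfinite(self.time).all():
            raise ValueError("non-finite survival time")
        if (self.time < 0).any():
            raise ValueError("negative survival time")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event flags must be 0/1")

    @classmethod
    def from_annotation(
        cls,
        annotation: pd.DataFrame,
        time_col: str = "dmfs_months",
        event_col: str = "event",
        covariate_cols=None,
    ) -> "SurvivalData":
        cov = annotation[list(covariate_cols)] if covariate_cols else None
        return cls(annotation[time_col], annotation[event_col], cov)


@dataclass
class KmCurve:
    """A Kaplan-Meier step function with at-risk counts."""

    times: np.ndarray                # event/censor times in ascending order
    survival: np.ndarray             # right-continuous S at those times
    at_risk: np.ndarray
    label: str = "KM"

    def survival_at(self, t: float) -> float:
        """Value of the right-continuous step function at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(data: SurvivalData, label: str = "KM") -> KmCurve:
    """Product-limit survival estimate."""
    if len(data.time) < 1:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, data.event, label=label)
    sf = kmf.survival_function_[label]
    times = sf.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KmCurve(times=times, survival=sf.to_numpy(), at_risk=at_risk, label=label)


def logrank(data: SurvivalData, groups) -> tuple[float, float]:
    """Log-rank test across >= 2 groups; returns (chi-square, p)."""
    groups = pd.Series(np.asarray(groups), index=data.time.index)
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if data.event.sum() == 0:
        raise ValueError("no events observed")
    if len(levels) == 2:
        a = groups == levels[0]
        res = logrank_test(
            data.time[a], data.time[~a], data.event[a], data.event[~a]
        )
    else:
        res = multivariate_logrank_test(data.time, groups, data.event)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(data: SurvivalData, robust: bool = False) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Wald p-values).

    Returns a DataFrame indexed by covariate with columns ``coef``, ``HR``,
    ``se``, ``p``.  Singular/separated designs surface as lifelines
    convergence errors.
    """
    if data.covariates is None or data.covariates.empty:
        raise ValueError("no covariates supplied")
    n_events = int(data.event.sum())
    if n_events < data.covariates.shape[1] + 5:
        raise ValueError("too few events for the number of covariates")
    df = data.covariates.copy()
    df["_time"] = data.time
    df["_event"] = data.event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event", robust=robust)
    out = pd.DataFrame(
        {
            "coef": cph.params_,
            "HR": np.exp(cph.params_),
            "se": cph.standard_errors_,
            "p": cph.summary["p"],
        }
    )
    out.index.name = "covariate"
    return out


def survival_at_5y(curve: KmCurve) -> float:
    """S(60 months).  If follow-up ends earlier the last value is returned
    with a warning."""
    import warnings

    if curve.times[-1] < FIVE_YEARS_MONTHS:
        warnings.warn("follow-up ends before 60 months; returning last KM value")
        return float(curve.survival[-1])
    return curve.survival_at(FIVE_YEARS_MONTHS)
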