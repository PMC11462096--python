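"""Kaplan-Meier cumulative incidence and per-document-type evaluation.

Time-to-onset is right-censored: a patient whose records never carry the
target term contributes follow-up time up to their last contact.  The
product-limit (Kaplan-Meier) estimator handles this; cumulative incidence is
1 − S(t).  Confidence intervals use Greenwood's variance on the log(−log)
scale, which keeps the band inside [0, 1].  Curves are evaluated on the
integer day grid 0..horizon — the finest grid whole-day data support.

Evaluation compares curves: the *detection gap* is the reference incidence
minus the system incidence in percentage points at a fixed day; the
*detection ratio* is their quotient; curve agreement over a window is the
Pearson correlation of the two daily series; and an ordinary least-squares
regression of the all-documents daily series on the per-document-type daily
series shows which document types drive the combined curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .corpus import DocType
from .timeline import PatientTimeline, onset_and_duration

__all__ = [
    "IncidenceCurve",
    "RegressionResult",
    "km_incidence",
    "per_doctype_curves",
    "detection_gap",
    "detection_ratio",
    "curve_correlation",
    "regress_all_on_per_doc",
    "read_reference_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IncidenceCurve:
    """Day-indexed cumulative incidence with 95% bounds and risk counts.

    ``incidence`` is a fraction in [0, 1]; ``day`` is the integer grid
    0..horizon.  Invariants: incidence is non-decreasing, the band contains
    the point estimate, and the number at risk is non-increasing.
    """

    day: np.ndarray
    incidence: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.day)
        if not (len(self.incidence) == len(self.ci_lower) == len(self.ci_upper)
                == len(self.n_at_risk) == n):
            raise ValueError("curve arrays must share one length")
        if np.any(np.diff(self.incidence) < -1e-12):
            raise ValueError("cumulative incidence must be non-decreasing")

    @property
    def horizon(self) -> int:
        return int(self.day[-1])

    def at(self, day: int) -> float:
        """Point estimate of cumulative incidence at an integer day."""
        if not (self.day[0] <= day <= self.day[-1]):
            raise ValueError(f"day {day} outside curve grid 0..{self.horizon}")
        return float(self.incidence[int(day) - int(self.day[0])])

    @classmethod
    def from_series(cls, day: Sequence[int], incidence: Sequence[float]) -> "IncidenceCurve":
        """Build a bare curve (no bands, no risk counts) from a daily series."""
        day = np.asarray(day, dtype=int)
        inc = np.asarray(incidence, dtype=float)
        zeros = np.zeros_like(inc)
        return cls(day=day, incidence=inc, ci_lower=inc.copy(), ci_upper=inc.copy(),
                   n_at_risk=zeros.astype(int))

    def to_frame(self, stratum: str = "all") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "estimate": self.incidence,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
                "n_at_risk": self.n_at_risk,
                "stratum": stratum,
            }
        )


def km_incidence(
    onset_days: Sequence[Optional[int]],
    censor_days: Sequence[int],
    horizon: int,
) -> IncidenceCurve:
    """Product-limit cumulative incidence of onset on the day grid 0..horizon.

    ``onset_days`` and ``censor_days`` are aligned per patient; an absent
    onset means the patient is censored at their censor day.  Ties (several
    onsets on one day) use the standard simultaneous-event product-limit
    formula.  Confidence intervals are Greenwood variance with the log(−log)
    transform.
    """
    if len(onset_days) != len(censor_days):
        raise ValueError("onset_days and censor_days must be aligned per patient")
    if len(onset_days) == 0:
        raise ValueError("empty cohort")
    durations = np.empty(len(onset_days), dtype=float)
    observed = np.empty(len(onset_days), dtype=bool)
    for i, (onset, censor) in enumerate(zip(onset_days, censor_days)):
        if censor < 0:
            raise ValueError(f"patient {i}: negative censor day {censor}")
        if onset is not None:
            if onset > censor:
                raise ValueError(f"patient {i}: onset day {onset} after censor day {censor}")
            durations[i], observed[i] = onset, True
        else:
            durations[i], observed[i] = censor, False

    grid = np.arange(horizon + 1)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    surv = kmf.survival_function_at_times(grid).to_numpy()

    # Step-interpolate the (log-log Greenwood) survival CI onto the day grid.
    ci = kmf.confidence_interval_survival_function_
    ci = ci.reindex(ci.index.union(grid)).ffill().loc[grid]
    surv_lower = ci.iloc[:, 0].to_numpy()
    surv_upper = ci.iloc[:, 1].to_numpy()

    n_at_risk = np.array([(durations >= t).sum() for t in grid])
    return IncidenceCurve(
        day=grid,
        incidence=1.0 - surv,
        ci_lower=1.0 - surv_upper,
        ci_upper=1.0 - surv_lower,
        n_at_risk=n_at_risk,
    )


def _onset_censor(timelines: Iterable[PatientTimeline]) -> tuple[list, list]:
    onsets, censors = [], []
    for tl in timelines:
        summary = onset_and_duration(tl)
        onsets.append(summary.onset_day)
        censors.append(tl.followup_end_day)
    return onsets, censors


def per_doctype_curves(
    timelines: Sequence[PatientTimeline],
    doc_types: Optional[Sequence[Union[DocType, str]]] = None,
    horizon: Optional[int] = None,
) -> dict[str, IncidenceCurve]:
    """One incidence curve per document type plus an ``"all"`` curve.

    For each document type the onset is recomputed restricting every
    patient's events to that type only; patients with no such events are
    censored at last contact.  Restricting the evidence can only delay or
    suppress onsets, so the all-documents curve dominates every per-type
    curve pointwise.
    """
    if doc_types is None:
        doc_types = list(DocType)
    doc_types = [DocType(dt) for dt in doc_types]
    if horizon is None:
        horizon = max(tl.followup_end_day for tl in timelines)

    curves: dict[str, IncidenceCurve] = {}
    onsets, censors = _onset_censor(timelines)
    curves["all"] = km_incidence(onsets, censors, horizon)
    for dt in doc_types:
        onsets, censors = _onset_censor(tl.restricted_to([dt]) for tl in timelines)
        curves[dt.value] = km_incidence(onsets, censors, horizon)
    return curves


def detection_gap(reference_pct: float, system_pct: float) -> float:
    """Reference minus system incidence, in percentage points.

    Negative values mean the system over-detects relative to the reference.
    """
    for name, v in (("reference_pct", reference_pct), ("system_pct", system_pct)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    return reference_pct - system_pct


def detection_ratio(
    system_curve: IncidenceCurve,
    reference_curve: IncidenceCurve,
    day: int,
) -> float:
    """System incidence divided by reference incidence at a fixed day."""
    ref = reference_curve.at(day)
    if ref <= 0.0:
        raise ZeroDivisionError(f"reference incidence is 0 at day {day}; ratio undefined")
    return system_curve.at(day) / ref


def curve_correlation(
    curve_a: IncidenceCurve,
    curve_b: IncidenceCurve,
    up_to_day: int,
) -> tuple[float, float]:
    """Pearson correlation of two daily incidence series over days 0..up_to_day."""
    for name, c in (("curve_a", curve_a), ("curve_b", curve_b)):
        if c.horizon < up_to_day:
            raise ValueError(f"{name} is not defined up to day {up_to_day}")
    a = curve_a.incidence[: up_to_day + 1]
    b = curve_b.incidence[: up_to_day + 1]
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("correlation undefined: at least one series is constant")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of the all-documents series on per-document series."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    intercept: float
    intercept_se: float
    dropped: tuple[str, ...]
    r_squared: float


def regress_all_on_per_doc(
    all_curve: IncidenceCurve,
    per_doc_curves: Mapping[str, IncidenceCurve],
    up_to_day: int,
) -> RegressionResult:
    """OLS of the all-documents daily series on the per-document daily series.

    Includes an intercept and reports conventional OLS standard errors.
    Constant or collinear predictor series are dropped with a logged warning
    before fitting; the fit on the remaining predictors is unchanged by the
    drop.
    """
    import statsmodels.api as sm

    y = all_curve.incidence[: up_to_day + 1]
    names, cols, dropped = [], [], []
    for name, curve in per_doc_curves.items():
        series = curve.incidence[: up_to_day + 1]
        if np.ptp(series) == 0.0:
            dropped.append(name)
            logger.warning("regress_all_on_per_doc: dropping constant predictor %r", name)
            continue
        candidate = np.column_stack(cols + [series]) if cols else series[:, None]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), candidate])) < candidate.shape[1] + 1:
            dropped.append(name)
            logger.warning("regress_all_on_per_doc: dropping collinear predictor %r", name)
            continue
        names.append(name)
        cols.append(series)
    if not cols:
        raise ValueError("no usable predictor series")
    X = sm.add_constant(np.column_stack(cols))
    if len(y) < X.shape[1] + 1:
        raise ValueError(f"{len(y)} observations cannot identify {X.shape[1]} parameters")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        coefficients=dict(zip(names, fit.params[1:])),
        std_errors=dict(zip(names, fit.bse[1:])),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        dropped=tuple(dropped),
        r_squared=float(fit.rsquared),
    )


def read_reference_curve(path) -> IncidenceCurve:
    """Load a reference curve from a (day, incidence) CSV.

    Incidence may be given as a fraction in [0, 1] or as a percentage in
    [0, 100]; values above 1 are interpreted as percentages.
    """
    df = pd.read_csv(path)
    day = df.iloc[:, 0].to_numpy(dtype=int)
    inc = df.iloc[:, 1].to_numpy(dtype=float)
    if np.nanmax(inc) > 1.0:
        inc = inc / 100.0
    return IncidenceCurve.from_series(day, inc)
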