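"""Calibration and discrimination metrics.

Observed event frequency, incidence rates, overestimation percentages, decile
calibration tables, Harrell's concordance statistic for censored survival
data (with bootstrap confidence interval) and ROC data export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import Cohort
from .engines import RiskPrediction
from .errors import DomainError

__all__ = [
    "CalibrationTable",
    "EvaluationReport",
    "ConcordanceResult",
    "observed_event_frequency",
    "incidence_rate",
    "overestimation_pct",
    "calibration_deciles",
    "harrells_c",
    "roc_export",
    "evaluate_predictions",
]


def _risk_array(predictions) -> np.ndarray:
    return np.asarray(
        [p.risk10 if isinstance(p, RiskPrediction) else float(p) for p in predictions],
        dtype=float,
    )


def _endpoint_arrays(cohort: Cohort, endpoint: str):
    times, events = [], []
    for s in cohort:
        t, ev = s.endpoint(endpoint)
        if t is None or ev is None:
            raise DomainError(
                f"subject {s.subject_id} lacks {endpoint} follow-up information"
            )
        times.append(t)
        events.append(ev)
    return np.asarray(times, dtype=float), np.asarray(events, dtype=bool)


# ---------------------------------------------------------------------------
# frequencies and rates
# ---------------------------------------------------------------------------


def observed_event_frequency(
    cohort: Cohort,
    endpoint: str = "ascvd",
    horizon: float = 10.0,
    method: str = "crude",
) -> float:
    """Observed event probability by ``horizon``.

    ``method="crude"`` (default) is the plain event proportion, events within
    the horizon divided by n.  ``method="km"`` returns one minus the
    product-limit (Kaplan-Meier) survival at the horizon, which adjusts for
    censoring before the horizon.
    """
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    times, events = _endpoint_arrays(cohort, endpoint)
    in_horizon = events & (times <= horizon)
    if method == "crude":
        return float(in_horizon.mean())
    if method == "km":
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter()
        kmf.fit(np.minimum(times, horizon), event_observed=in_horizon)
        return float(1.0 - kmf.predict(horizon))
    raise ValueError(f"unknown method {method!r}")


def incidence_rate(cohort: Cohort, endpoint: str = "ascvd") -> float:
    """Events per 1,000 person-years: 1000 x event count / total follow-up."""
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    times, events = _endpoint_arrays(cohort, endpoint)
    person_years = float(times.sum())
    if person_years <= 0:
        raise DomainError("total person-years is zero")
    return 1000.0 * float(events.sum()) / person_years


def overestimation_pct(estimated_rate: float, observed_rate: float) -> float:
    """[(estimated / observed) - 1] x 100; positive means overestimation."""
    if observed_rate <= 0:
        raise DomainError(f"observed rate must be positive, got {observed_rate}")
    return (estimated_rate / observed_rate - 1.0) * 100.0


# ---------------------------------------------------------------------------
# decile calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationTable:
    """Per-decile mean predicted risk versus observed event frequency."""

    table: pd.DataFrame  # columns: group, n, mean_pred, observed_freq
    n: int
    total_mean_pred: float
    total_observed: float
    has_ties: bool = False

    def to_csv(self, path) -> None:
        out = self.table.copy()
        totals = pd.DataFrame(
            [{"group": "total", "n": self.n, "mean_pred": self.total_mean_pred,
              "observed_freq": self.total_observed}]
        )
        pd.concat([out, totals], ignore_index=True).to_csv(path, index=False)


def calibration_deciles(
    predictions,
    outcomes: Sequence[bool],
    n_groups: int = 10,
) -> CalibrationTable:
    """Group subjects into deciles of predicted risk and compare means.

    Subjects are ranked by prediction and split into ``n_groups`` rank-based
    quantile groups; tied predictions are kept together in the group of the
    first tied subject, so group sizes differ by at most one except under
    ties.  Observed frequency per group is the crude event proportion.
    """
    risks = _risk_array(predictions)
    ev = np.asarray(outcomes, dtype=bool)
    n = risks.size
    if n < n_groups:
        raise DomainError(
            f"need at least {n_groups} subjects for {n_groups} groups, got {n}"
        )
    order = np.argsort(risks, kind="stable")
    sorted_r = risks[order]
    sorted_e = ev[order]
    # rank-based group, then pull every tie run into the group of its first member
    group = (np.arange(n) * n_groups) // n
    has_ties = False
    start = 0
    while start < n:
        end = start
        while end + 1 < n and sorted_r[end + 1] == sorted_r[start]:
            end += 1
        if group[end] != group[start]:
            has_ties = True
            group[start : end + 1] = group[start]
        start = end + 1
    rows = []
    for g in np.unique(group):
        mask = group == g
        rows.append(
            {
                "group": int(g) + 1,
                "n": int(mask.sum()),
                "mean_pred": float(sorted_r[mask].mean()),
                "observed_freq": float(sorted_e[mask].mean()),
            }
        )
    table = pd.DataFrame(rows)
    return CalibrationTable(
        table=table,
        n=n,
        total_mean_pred=float(risks.mean()),
        total_observed=float(ev.mean()),
        has_ties=has_ties,
    )


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_usable: float = 0.0
    bootstrap: int = 0


def _concordance_counts(risks: np.ndarray, times: np.ndarray, events: np.ndarray):
    """(weighted concordant, usable) pair counts under Harrell's rules.

    A pair is usable iff the smaller observed time carries an event; equal
    times are usable only when both are events and then contribute 0.5.
    Prediction ties among usable pairs contribute 0.5.
    """
    n = times.size
    order = np.argsort(times, kind="stable")
    t = times[order]
    p = risks[order]
    e = events[order]
    usable = 0.0
    score = 0.0
    start = 0
    while start < n:
        end = start
        while end + 1 < n and t[end + 1] == t[start]:
            end += 1
        ne = int(e[start : end + 1].sum())
        tie_pairs = ne * (ne - 1) / 2.0
        usable += tie_pairs
        score += 0.5 * tie_pairs
        suffix = p[end + 1 :]
        if suffix.size:
            for i in range(start, end + 1):
                if e[i]:
                    usable += suffix.size
                    score += float((suffix < p[i]).sum()) + 0.5 * float(
                        (suffix == p[i]).sum()
                    )
        start = end + 1
    return score, usable


def harrells_c(
    predictions,
    times,
    events,
    bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Harrell's concordance statistic for censored data, with bootstrap CI.

    Concordance is the probability that of a usable pair the subject with the
    earlier event carries the higher predicted risk; prediction ties count
    one half.  The confidence interval is a seeded nonparametric percentile
    bootstrap over subjects (``bootstrap`` resamples; 0 skips the interval).
    """
    risks = _risk_array(predictions)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (risks.size == t.size == e.size):
        raise DomainError("predictions, times and events must align")
    score, usable = _concordance_counts(risks, t, e)
    if usable == 0:
        raise DomainError("no usable pairs (no events, or all ties at censored times)")
    c = score / usable
    if bootstrap <= 0:
        return ConcordanceResult(c=c, n_usable=usable)
    rng = np.random.default_rng(seed)
    n = risks.size
    stats = np.empty(bootstrap, dtype=float)
    for b in range(bootstrap):
        idx = rng.integers(0, n, size=n)
        s_b, u_b = _concordance_counts(risks[idx], t[idx], e[idx])
        stats[b] = s_b / u_b if u_b > 0 else np.nan
    stats = stats[~np.isnan(stats)]
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ConcordanceResult(c=c, ci_low=float(lo), ci_high=float(hi),
                             n_usable=usable, bootstrap=bootstrap)


# ---------------------------------------------------------------------------
# ROC export
# ---------------------------------------------------------------------------


def roc_export(predictions, event_by_horizon: Sequence[bool]):
    """Empirical ROC curve and trapezoidal AUC for the dichotomized outcome.

    Returns ``(DataFrame with fpr/tpr/threshold columns, auc)``.  Thresholds
    are the distinct prediction values.
    """
    from sklearn.metrics import roc_curve

    risks = _risk_array(predictions)
    y = np.asarray(event_by_horizon, dtype=bool)
    if y.all() or not y.any():
        raise DomainError("both classes must be present to compute an ROC curve")
    fpr, tpr, thr = roc_curve(y, risks, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Summary of one equation on one stratum (percent scale for rates)."""

    equation: str
    stratum: str
    n: int
    n_events: int
    observed_freq: float          # %
    mean_estimated: float         # %
    overestimation: float         # %
    c_statistic: float
    c_ci_low: Optional[float]
    c_ci_high: Optional[float]
    incidence_rate: float         # events per 1,000 person-years
    calibration: Optional[CalibrationTable] = None

    def to_row(self) -> dict:
        return {
            "stratum": self.stratum,
            "equation": self.equation,
            "n": self.n,
            "events": self.n_events,
            "observed_freq_pct": round(self.observed_freq, 1),
            "estimated_risk_pct": round(self.mean_estimated, 1),
            "overestimation_pct": round(self.overestimation, 1),
            "c_statistic": round(self.c_statistic, 2),
            "c_ci_low": None if self.c_ci_low is None else round(self.c_ci_low, 2),
            "c_ci_high": None if self.c_ci_high is None else round(self.c_ci_high, 2),
            "incidence_per_1000py": round(self.incidence_rate, 1),
            "observed_freq_pct_full": self.observed_freq,
            "estimated_risk_pct_full": self.mean_estimated,
            "overestimation_pct_full": self.overestimation,
            "c_statistic_full": self.c_statistic,
        }


def evaluate_predictions(
    cohort: Cohort,
    predictions,
    equation: str,
    stratum: str = "total",
    endpoint: str = "ascvd",
    horizon: float = 10.0,
    freq_method: str = "crude",
    bootstrap: int = 1000,
    seed: int = 0,
    with_calibration: bool = True,
) -> EvaluationReport:
    """Assemble the full calibration/discrimination report for one stratum."""
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    risks = _risk_array(predictions)
    if risks.size != len(cohort):
        raise DomainError("one prediction per subject required")
    times, events = _endpoint_arrays(cohort, endpoint)
    in_horizon = events & (times <= horizon)
    observed = observed_event_frequency(cohort, endpoint, horizon, method=freq_method)
    mean_est = float(risks.mean())
    over = overestimation_pct(100.0 * mean_est, 100.0 * observed)
    conc = harrells_c(risks, times, events, bootstrap=bootstrap, seed=seed)
    rate = incidence_rate(cohort, endpoint)
    calib = None
    if with_calibration and len(cohort) >= 10:
        calib = calibration_deciles(risks, in_horizon)
    return EvaluationReport(
        equation=equation,
        stratum=stratum,
        n=len(cohort),
        n_events=int(in_horizon.sum()),
        observed_freq=100.0 * observed,
        mean_estimated=100.0 * mean_est,
        overestimation=over,
        c_statistic=conc.c,
        c_ci_low=conc.ci_low,
        c_ci_high=conc.ci_high,
        incidence_rate=rate,
        calibration=calib,
    )
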