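"""Intercept-level recalibration ("calibration in the large") and k-fold CV.

The correction factor is the log odds-ratio of the observed event frequency
to the mean predicted risk,

    c = ln[ (O / (1 - O)) / (Pbar / (1 - Pbar)) ],

applied by default as a logit shift of each predicted risk.  An alternative
mode shifts the exponent of the survival-form equation instead (multiplying
``exp(LP - mean_lp)`` by ``e**c``); both modes realize c = 0 as the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .cohort import Cohort
from .engines import PceEquation, Recalibration, RiskPrediction
from .errors import DegenerateInputError, DomainError

__all__ = [
    "RecalibrationFactor",
    "compute_correction",
    "apply_correction",
    "recalibrate_equation",
    "kfold_cross_validate",
]


@dataclass(frozen=True)
class RecalibrationFactor:
    """Correction factor with the summary statistics that produced it."""

    correction: float
    observed_freq: float
    mean_pred: float
    n: int
    source_label: str = ""


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def compute_correction(
    predictions: Sequence[Union[RiskPrediction, float]],
    outcomes: Sequence[bool],
    source_label: str = "",
) -> RecalibrationFactor:
    """Correction factor from predictions and event-by-horizon indicators.

    ``O`` is the crude event proportion and ``Pbar`` the arithmetic mean of
    the predicted risks; both must lie strictly inside (0, 1).
    """
    risks = np.asarray(
        [p.risk10 if isinstance(p, RiskPrediction) else float(p) for p in predictions],
        dtype=float,
    )
    ev = np.asarray(outcomes, dtype=bool)
    if risks.shape != ev.shape:
        raise DomainError(
            f"predictions ({risks.size}) and outcomes ({ev.size}) must align"
        )
    if risks.size == 0:
        raise DomainError("empty input")
    observed = float(ev.mean())
    mean_pred = float(risks.mean())
    for label, v in (("observed frequency", observed), ("mean predicted risk", mean_pred)):
        if not 0.0 < v < 1.0:
            raise DegenerateInputError(
                f"{label} is {v}; log-odds undefined (need at least one event "
                f"and one non-event, predictions strictly inside (0,1))"
            )
    c = math.log(observed / (1.0 - observed)) - math.log(mean_pred / (1.0 - mean_pred))
    return RecalibrationFactor(c, observed, mean_pred, int(risks.size), source_label)


def apply_correction(p, f: Union[RecalibrationFactor, float]):
    """Shift probability ``p`` by the correction on the logit scale.

    Accepts a scalar or array of probabilities strictly inside (0, 1).
    Strictly increasing in ``p``; identity when the correction is zero.
    """
    c = f.correction if isinstance(f, RecalibrationFactor) else float(f)
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DegenerateInputError("probabilities must lie strictly inside (0,1)")
    out = _expit(_logit(arr) + c)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def recalibrate_equation(
    eq: PceEquation,
    training: Cohort,
    endpoint: str = "ascvd",
    source_label: Optional[str] = None,
    mode: str = "logit",
    name: str = "pce_recalibrated",
) -> PceEquation:
    """Return a recalibrated copy of ``eq`` trained on a cohort.

    The training cohort must have passed exclusions and horizon censoring for
    the chosen endpoint; its event indicators define the observed frequency.
    The original equation is untouched.
    """
    preds = eq.predict_cohort(training)
    outcomes = []
    for s in training:
        _, ev = s.endpoint(endpoint)
        if ev is None:
            raise DomainError(
                f"subject {s.subject_id} has unknown {endpoint} event status; "
                "apply exclusions before recalibrating"
            )
        outcomes.append(ev)
    factor = compute_correction(preds, outcomes, source_label=source_label or training.name)
    recal = Recalibration(
        correction=factor.correction,
        observed_freq=factor.observed_freq,
        mean_pred=factor.mean_pred,
        training_label=factor.source_label,
        mode=mode,
    )
    return eq.with_recalibration(recal, name=name)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _stratified_folds(events: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign fold labels 0..k-1, event-stratified and size-balanced.

    Events are dealt round-robin first, then non-events continue the deal, so
    events spread maximally across folds and no fold is left empty.
    """
    order = np.concatenate(
        [rng.permutation(np.flatnonzero(events)), rng.permutation(np.flatnonzero(~events))]
    )
    folds = np.empty(events.size, dtype=int)
    folds[order] = np.arange(events.size) % k
    return folds


def kfold_cross_validate(
    cohort: Cohort,
    eq: PceEquation,
    k: int = 10,
    seed: int = 0,
    endpoint: str = "ascvd",
    mode: str = "logit",
) -> dict:
    """Event-stratified k-fold cross-validation of the recalibration.

    For each fold the correction is computed on the other k-1 folds and the
    held-out fold is scored with the recalibrated equation; overestimation and
    Harrell's C (no bootstrap) are reported per fold, plus a pooled summary
    averaging the fold metrics.  Deterministic given ``seed``.
    """
    from .evaluate import harrells_c, observed_event_frequency, overestimation_pct

    if k < 2:
        raise DomainError("k must be at least 2")
    n = len(cohort)
    if n < k:
        raise DomainError(f"cohort size {n} smaller than k={k}")

    events = []
    times = []
    for s in cohort:
        t, ev = s.endpoint(endpoint)
        if ev is None or t is None:
            raise DomainError(f"subject {s.subject_id} lacks {endpoint} follow-up data")
        events.append(ev)
        times.append(t)
    events = np.asarray(events, dtype=bool)
    times = np.asarray(times, dtype=float)

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(events, k, rng)

    base_preds = np.asarray([p.risk10 for p in eq.predict_cohort(cohort)], dtype=float)

    fold_reports = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        if not events[train].any() or events[train].all():
            raise DomainError(f"degenerate training split for fold {fold}; reduce k")
        factor = compute_correction(base_preds[train], events[train],
                                    source_label=f"{cohort.name}/cv-fold-{fold}")
        if mode == "logit":
            recal_preds = apply_correction(base_preds[test], factor)
        else:
            sub = [s for s, m in zip(cohort.subjects, test) if m]
            recal_eq = eq.with_recalibration(
                Recalibration(factor.correction, factor.observed_freq,
                              factor.mean_pred, factor.source_label, mode=mode)
            )
            recal_preds = np.asarray(
                [recal_eq.predict(s).risk10 for s in sub], dtype=float
            )
        observed = float(events[test].mean())
        mean_est = float(recal_preds.mean())
        over = overestimation_pct(100.0 * mean_est, 100.0 * observed) if observed > 0 else math.nan
        try:
            c_stat = harrells_c(recal_preds, times[test], events[test], bootstrap=0).c
        except DomainError:  # tiny held-out fold without usable pairs (e.g. LOO)
            c_stat = math.nan
        fold_reports.append(
            {
                "fold": fold,
                "n": int(test.sum()),
                "events": int(events[test].sum()),
                "correction": factor.correction,
                "observed_freq": observed,
                "mean_estimated": mean_est,
                "overestimation_pct": over,
                "c_statistic": c_stat,
            }
        )

    overs = [fr["overestimation_pct"] for fr in fold_reports if not math.isnan(fr["overestimation_pct"])]
    cs = [fr["c_statistic"] for fr in fold_reports if not math.isnan(fr["c_statistic"])]
    summary = {
        "k": k,
        "seed": seed,
        "mean_overestimation_pct": float(np.mean(overs)) if overs else math.nan,
        "mean_abs_overestimation_pct": float(np.mean(np.abs(overs))) if overs else math.nan,
        "mean_c_statistic": float(np.mean(cs)) if cs else math.nan,
        "mean_correction": float(np.mean([fr["correction"] for fr in fold_reports])),
    }
    return {"folds": fold_reports, "summary": summary}
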