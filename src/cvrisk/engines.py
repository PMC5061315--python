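"""Closed-form 10-year risk equations.

Two engines are provided:

* the pooled-cohort ASCVD equation (proportional-hazards form,
  ``risk = 1 - s0_10 ** exp(LP - mean_lp)``), sex-stratified with log-scale
  covariate terms and treated/untreated blood-pressure branches; and
* the European cardiovascular-mortality equation (cause-specific Weibull
  baseline survival for CHD and non-CHD causes combined by summation).

Coefficients are loaded from versioned JSON constants files; the defaults
shipped with the package cover the white/Caucasian strata and the low-risk
country variant.  A loaded equation may carry a ``recalibration`` block (see
:mod:`cvrisk.recalibrate`) which shifts predictions on the logit scale (or,
in the alternative mode, inside the survival exponent).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort import Cohort, Sex, SubjectRecord, chol_mgdl_to_mmoll
from .errors import CvriskError, DomainError, FormatError

__all__ = [
    "PceCoefficientSet",
    "EscCauseParams",
    "EscCoefficientSet",
    "RiskPrediction",
    "PceEquation",
    "EscEquation",
    "pce_linear_predictor",
    "pce_risk10",
    "esc_risk10",
    "load_default_pce",
    "load_default_esc",
    "load_equation",
]

PCE_TERM_NAMES = (
    "ln_age",
    "ln_age_sq",
    "ln_tc",
    "ln_age_ln_tc",
    "ln_hdl",
    "ln_age_ln_hdl",
    "ln_sbp_treated",
    "ln_sbp_untreated",
    "ln_age_ln_sbp_treated",
    "ln_age_ln_sbp_untreated",
    "smoker",
    "ln_age_smoker",
    "diabetes",
)


@dataclass(frozen=True)
class PceCoefficientSet:
    """Per-sex coefficients, mean linear predictor and baseline survival."""

    sex: Sex
    terms: dict
    mean_lp: float
    s0_10: float
    race: Optional[str] = None

    def __post_init__(self):
        if not 0.0 < self.s0_10 < 1.0:
            raise DomainError(f"s0_10 must be in (0,1), got {self.s0_10}")
        unknown = set(self.terms) - set(PCE_TERM_NAMES)
        if unknown:
            raise FormatError(f"unknown coefficient term(s): {sorted(unknown)}")

    def coef(self, name: str) -> float:
        return float(self.terms.get(name, 0.0))


@dataclass(frozen=True)
class EscCauseParams:
    alpha: float
    p: float
    beta_smoker: float
    beta_chol: float
    beta_sbp: float

    def __post_init__(self):
        if not self.p > 0:
            raise DomainError(f"Weibull shape p must be positive, got {self.p}")


@dataclass(frozen=True)
class EscCoefficientSet:
    """Per-sex, per-cause Weibull parameters and risk-factor coefficients."""

    sex: Sex
    causes: dict  # cause name -> EscCauseParams
    reference_chol: float = 6.0
    reference_sbp: float = 120.0


@dataclass(frozen=True)
class RiskPrediction:
    subject_id: str
    equation: str
    risk10: float
    linear_predictor: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.risk10 <= 1.0:
            raise DomainError(f"risk10 out of [0,1]: {self.risk10}")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _check_positive(s: SubjectRecord, names):
    for n in names:
        v = getattr(s, n)
        if v is None or not v > 0:
            raise DomainError(f"{n} must be positive and known, got {v} "
                              f"(subject {s.subject_id})")


def pce_linear_predictor(s: SubjectRecord, c: PceCoefficientSet) -> float:
    """Linear predictor: sum of coefficient x term over the log-scale terms.

    The treated blood-pressure terms apply iff ``bp_treated``; absent terms
    carry coefficient zero.
    """
    if s.sex != c.sex:
        raise CvriskError(
            f"coefficient set is for {c.sex.value}, subject {s.subject_id} is {s.sex.value}"
        )
    _check_positive(s, ("age", "total_chol", "hdl_chol", "sbp"))
    if s.bp_treated is None or s.smoker is None or s.diabetes is None:
        raise DomainError(f"bp_treated/smoker/diabetes must be known (subject {s.subject_id})")
    ln_age = math.log(s.age)
    ln_tc = math.log(s.total_chol)
    ln_hdl = math.log(s.hdl_chol)
    ln_sbp = math.log(s.sbp)
    smoker = 1.0 if s.smoker else 0.0
    lp = (
        c.coef("ln_age") * ln_age
        + c.coef("ln_age_sq") * ln_age * ln_age
        + c.coef("ln_tc") * ln_tc
        + c.coef("ln_age_ln_tc") * ln_age * ln_tc
        + c.coef("ln_hdl") * ln_hdl
        + c.coef("ln_age_ln_hdl") * ln_age * ln_hdl
        + c.coef("smoker") * smoker
        + c.coef("ln_age_smoker") * ln_age * smoker
        + c.coef("diabetes") * (1.0 if s.diabetes else 0.0)
    )
    if s.bp_treated:
        lp += c.coef("ln_sbp_treated") * ln_sbp
        lp += c.coef("ln_age_ln_sbp_treated") * ln_age * ln_sbp
    else:
        lp += c.coef("ln_sbp_untreated") * ln_sbp
        lp += c.coef("ln_age_ln_sbp_untreated") * ln_age * ln_sbp
    return lp


def pce_risk10(s: SubjectRecord, c: PceCoefficientSet) -> float:
    """10-year risk ``1 - s0_10 ** exp(LP - mean_lp)``."""
    lp = pce_linear_predictor(s, c)
    return 1.0 - c.s0_10 ** math.exp(lp - c.mean_lp)


def _esc_baseline_survival(age: float, cp: EscCauseParams) -> float:
    return math.exp(-math.exp(cp.alpha) * (age - 20.0) ** cp.p)


def esc_risk10(s: SubjectRecord, c: EscCoefficientSet, combine: str = "sum") -> float:
    """10-year cardiovascular mortality risk.

    For each cause the baseline survival is ``exp(-exp(alpha) * (age-20)**p)``
    and the risk-factor weight ``w = exp(beta terms at deviations from the
    reference profile)``; the cause risk is ``1 - (S0(age+10)/S0(age)) ** w``.
    Cause risks are summed and capped at 1 (default) or combined as
    ``1-(1-r1)(1-r2)`` with ``combine="independent"``.
    """
    if s.sex != c.sex:
        raise CvriskError(
            f"coefficient set is for {c.sex.value}, subject {s.subject_id} is {s.sex.value}"
        )
    if s.age is None or s.age <= 20:
        raise DomainError(f"age must exceed 20 years, got {s.age}")
    _check_positive(s, ("total_chol", "sbp"))
    if s.smoker is None:
        raise DomainError(f"smoker must be known (subject {s.subject_id})")
    chol = chol_mgdl_to_mmoll(s.total_chol)
    smoker = 1.0 if s.smoker else 0.0
    risks = []
    for cp in c.causes.values():
        s_now = _esc_baseline_survival(s.age, cp)
        s_10 = _esc_baseline_survival(s.age + 10.0, cp)
        w = math.exp(
            cp.beta_chol * (chol - c.reference_chol)
            + cp.beta_sbp * (s.sbp - c.reference_sbp)
            + cp.beta_smoker * smoker
        )
        risks.append(1.0 - (s_10 / s_now) ** w)
    if combine == "sum":
        return min(1.0, sum(risks))
    if combine == "independent":
        surv = 1.0
        for r in risks:
            surv *= 1.0 - r
        return 1.0 - surv
    raise ValueError(f"unknown combine mode {combine!r}")


# ---------------------------------------------------------------------------
# equation objects (sex dispatch + optional recalibration block)
# ---------------------------------------------------------------------------


@dataclass
class Recalibration:
    """Serializable intercept-level correction attached to an equation."""

    correction: float
    observed_freq: float
    mean_pred: float
    training_label: str
    mode: str = "logit"  # or "exponent"

    def to_json(self) -> dict:
        return {
            "correction": self.correction,
            "observed_freq": self.observed_freq,
            "mean_pred": self.mean_pred,
            "training_label": self.training_label,
            "mode": self.mode,
        }

    @classmethod
    def from_json(cls, d: dict) -> "Recalibration":
        return cls(
            correction=float(d["correction"]),
            observed_freq=float(d["observed_freq"]),
            mean_pred=float(d["mean_pred"]),
            training_label=str(d.get("training_label", "")),
            mode=str(d.get("mode", "logit")),
        )


def _shift_logit(p: float, c: float) -> float:
    if not 0.0 < p < 1.0:
        raise DomainError(f"probability must be in (0,1) to shift, got {p}")
    return 1.0 / (1.0 + math.exp(-(math.log(p / (1.0 - p)) + c)))


class PceEquation:
    """Sex-dispatching pooled-cohort equation, optionally recalibrated."""

    def __init__(self, strata: dict, name: str = "pce_original",
                 version: str = "", source: str = "",
                 recalibration: Optional[Recalibration] = None):
        self.strata = strata  # Sex -> PceCoefficientSet
        self.name = name
        self.version = version
        self.source = source
        self.recalibration = recalibration

    def stratum(self, sex: Sex) -> PceCoefficientSet:
        try:
            return self.strata[sex]
        except KeyError:
            raise CvriskError(f"no coefficient stratum for sex {sex.value}") from None

    def predict(self, s: SubjectRecord) -> RiskPrediction:
        c = self.stratum(s.sex)
        lp = pce_linear_predictor(s, c)
        if self.recalibration is not None and self.recalibration.mode == "exponent":
            risk = 1.0 - c.s0_10 ** math.exp(lp - c.mean_lp + self.recalibration.correction)
        else:
            risk = 1.0 - c.s0_10 ** math.exp(lp - c.mean_lp)
            if self.recalibration is not None:
                risk = _shift_logit(risk, self.recalibration.correction)
        return RiskPrediction(s.subject_id, self.name, risk, linear_predictor=lp)

    def predict_cohort(self, cohort: Cohort) -> list[RiskPrediction]:
        return [self.predict(s) for s in cohort]

    def with_recalibration(self, recal: Recalibration, name: str = "pce_recalibrated") -> "PceEquation":
        return PceEquation(self.strata, name=name, version=self.version,
                           source=self.source, recalibration=recal)

    # serialization -------------------------------------------------------

    def to_json(self) -> dict:
        d = {
            "equation": "pce",
            "version": self.version,
            "source_citation": self.source,
            "strata": [
                {
                    "sex": cs.sex.value,
                    **({"race": cs.race} if cs.race else {}),
                    "terms": dict(cs.terms),
                    "mean_lp": cs.mean_lp,
                    "s0_10": cs.s0_10,
                }
                for cs in self.strata.values()
            ],
        }
        if self.recalibration is not None:
            d["recalibration"] = self.recalibration.to_json()
        return d

    @classmethod
    def from_json(cls, d: dict) -> "PceEquation":
        strata = {}
        for st in d["strata"]:
            sex = Sex(st["sex"])
            strata[sex] = PceCoefficientSet(
                sex=sex,
                terms={k: float(v) for k, v in st["terms"].items()},
                mean_lp=float(st["mean_lp"]),
                s0_10=float(st["s0_10"]),
                race=st.get("race"),
            )
        recal = None
        name = "pce_original"
        if "recalibration" in d:
            recal = Recalibration.from_json(d["recalibration"])
            name = "pce_recalibrated"
        return cls(strata, name=name, version=d.get("version", ""),
                   source=d.get("source_citation", ""), recalibration=recal)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n", encoding="utf-8")


class EscEquation:
    """Sex-dispatching cardiovascular-mortality equation."""

    def __init__(self, strata: dict, name: str = "esc_low_risk",
                 version: str = "", source: str = "", combine: str = "sum"):
        self.strata = strata  # Sex -> EscCoefficientSet
        self.name = name
        self.version = version
        self.source = source
        self.combine = combine

    def stratum(self, sex: Sex) -> EscCoefficientSet:
        try:
            return self.strata[sex]
        except KeyError:
            raise CvriskError(f"no coefficient stratum for sex {sex.value}") from None

    def predict(self, s: SubjectRecord) -> RiskPrediction:
        risk = esc_risk10(s, self.stratum(s.sex), combine=self.combine)
        return RiskPrediction(s.subject_id, self.name, risk)

    def predict_cohort(self, cohort: Cohort) -> list[RiskPrediction]:
        return [self.predict(s) for s in cohort]

    @classmethod
    def from_json(cls, d: dict) -> "EscEquation":
        strata = {}
        for st in d["strata"]:
            sex = Sex(st["sex"])
            causes = {
                cname: EscCauseParams(
                    alpha=float(cp["alpha"]),
                    p=float(cp["p"]),
                    beta_smoker=float(cp["beta_smoker"]),
                    beta_chol=float(cp["beta_chol"]),
                    beta_sbp=float(cp["beta_sbp"]),
                )
                for cname, cp in st["causes"].items()
            }
            strata[sex] = EscCoefficientSet(
                sex=sex,
                causes=causes,
                reference_chol=float(d.get("reference_chol_mmoll", 6.0)),
                reference_sbp=float(d.get("reference_sbp_mmhg", 120.0)),
            )
        return cls(strata, version=d.get("version", ""), source=d.get("source_citation", ""))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _load_json(path_or_resource) -> dict:
    return json.loads(Path(path_or_resource).read_text(encoding="utf-8"))


def load_equation(path):
    """Load an equation from a JSON constants file, dispatching on its kind."""
    d = _load_json(path)
    kind = d.get("equation")
    if kind == "pce":
        return PceEquation.from_json(d)
    if kind == "esc_score":
        return EscEquation.from_json(d)
    raise FormatError(f"unknown equation kind {kind!r} in {path}")


def _default_path(filename: str) -> Path:
    return Path(resources.files("cvrisk").joinpath("data", filename))


def load_default_pce() -> PceEquation:
    """Default pooled-cohort equation (white strata)."""
    return PceEquation.from_json(_load_json(_default_path("pce_caucasian.json")))


def load_default_esc() -> EscEquation:
    """Default cardiovascular-mortality equation (low-risk region)."""
    return EscEquation.from_json(_load_json(_default_path("esc_low_risk.json")))


def predictions_to_frame(preds: list[RiskPrediction]):
    """Tabulate predictions as a pandas DataFrame (subject_id, equation, risk10, lp)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in preds],
            "equation": [p.equation for p in preds],
            "risk10": np.array([p.risk10 for p in preds], dtype=float),
            "linear_predictor": [
                p.linear_predictor if p.linear_predictor is not None else np.nan
                for p in preds
            ],
        }
    )
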