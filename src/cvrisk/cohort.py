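"""Cohort data model, delimited-text I/O, unit conversion and exclusion filters.

A cohort is an ordered collection of :class:`SubjectRecord` plus an exclusion
log.  Files are UTF-8 delimited text (comma by default, tab accepted) with one
header row; empty cells denote unknown values.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import DomainError, FormatError, RowError

__all__ = [
    "Sex",
    "SubjectRecord",
    "Cohort",
    "ExclusionConfig",
    "COLUMNS",
    "read_cohort",
    "write_cohort",
    "chol_mgdl_to_mmoll",
    "apply_exclusions",
    "censor_at_horizon",
]

#: mg/dL of total cholesterol per mmol/L.
MGDL_PER_MMOLL = 38.67

#: Documented column order of the cohort file format.
COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "total_chol_mgdl",
    "hdl_mgdl",
    "sbp_mmhg",
    "bp_treated",
    "smoker",
    "diabetes",
    "prev_chf",
    "prev_mi",
    "prev_stroke",
    "fu_ascvd_years",
    "event_ascvd",
    "fu_cvdeath_years",
    "event_cvdeath",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, token: str) -> "Sex":
        t = token.strip().upper()
        if t in ("M", "MALE"):
            return cls.MALE
        if t in ("F", "FEMALE"):
            return cls.FEMALE
        raise ValueError(f"unrecognised sex code {token!r} (expected M or F)")

    @property
    def code(self) -> str:
        return "M" if self is Sex.MALE else "F"


@dataclass
class SubjectRecord:
    """One participant's risk factors, follow-up times and endpoint indicators.

    Unknown values are represented as ``None``.  Units: age in years, total
    and HDL cholesterol in mg/dL, systolic blood pressure in mmHg, follow-up
    times in years.
    """

    subject_id: str
    sex: Sex
    age: float
    total_chol: float
    hdl_chol: float
    sbp: float
    bp_treated: Optional[bool]
    smoker: Optional[bool]
    diabetes: Optional[bool]
    prev_chf: Optional[bool] = None
    prev_mi: Optional[bool] = None
    prev_stroke: Optional[bool] = None
    fu_time_ascvd: Optional[float] = None
    event_ascvd: Optional[bool] = None
    fu_time_cvdeath: Optional[float] = None
    event_cvdeath: Optional[bool] = None

    def validate(self) -> None:
        for name in ("age", "total_chol", "hdl_chol", "sbp"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"{name} must be positive, got {v}")
        for fu, ev in (
            ("fu_time_ascvd", "event_ascvd"),
            ("fu_time_cvdeath", "event_cvdeath"),
        ):
            t = getattr(self, fu)
            e = getattr(self, ev)
            if t is not None and t < 0:
                raise DomainError(f"{fu} must be non-negative, got {t}")
            if e is None and t is not None:
                raise DomainError(
                    f"{ev} unknown but {fu} present for subject {self.subject_id}"
                )

    # endpoint accessors -------------------------------------------------

    def endpoint(self, which: str) -> tuple[Optional[float], Optional[bool]]:
        """Return ``(follow-up time, event indicator)`` for an endpoint name."""
        if which == "ascvd":
            return self.fu_time_ascvd, self.event_ascvd
        if which == "cv_death":
            return self.fu_time_cvdeath, self.event_cvdeath
        raise ValueError(f"unknown endpoint {which!r}")


#: Order in which exclusion criteria claim a subject; each removed subject is
#: logged under the first criterion that matches.
EXCLUSION_ORDER = ("age", "prevalent_disease", "missing_endpoint", "missing_risk_factor")

ENDPOINT_FIELDS = frozenset(
    {"fu_time_ascvd", "event_ascvd", "fu_time_cvdeath", "event_cvdeath"}
)

DEFAULT_REQUIRED = frozenset(
    {
        "total_chol",
        "hdl_chol",
        "sbp",
        "bp_treated",
        "smoker",
        "diabetes",
        "fu_time_ascvd",
        "event_ascvd",
    }
)

#: Completeness set for the cardiovascular-mortality endpoint variant.
ESC_REQUIRED = frozenset(
    {"total_chol", "sbp", "smoker", "fu_time_cvdeath", "event_cvdeath"}
)


@dataclass(frozen=True)
class ExclusionConfig:
    """Eligibility filter: age window, prevalent-disease flags, completeness.

    Unknown prevalent-disease flags do *not* exclude; only an explicit True
    does.  ``require_complete`` names SubjectRecord fields that must be known.
    """

    age_min: float = 40.0
    age_max: float = 79.0
    exclude_prevalent: frozenset = frozenset({"chf", "mi", "stroke"})
    require_complete: frozenset = DEFAULT_REQUIRED

    def __post_init__(self):
        if not self.age_min < self.age_max:
            raise DomainError("age_min must be strictly below age_max")

    @classmethod
    def esc_default(cls) -> "ExclusionConfig":
        """Variant requiring completeness of the mortality endpoint fields.

        The published criteria for the mortality-score sample are not fully
        documented, so this is a parameterized stand-in, not an assertion.
        """
        return cls(require_complete=ESC_REQUIRED)


@dataclass
class Cohort:
    """Named, ordered collection of subjects with an exclusion log."""

    name: str
    subjects: list[SubjectRecord] = field(default_factory=list)
    exclusion_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def validate(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate subject_ids in cohort {self.name!r}")
        for s in self.subjects:
            s.validate()


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _parse_bool(token: str) -> Optional[bool]:
    t = token.strip()
    if t == "":
        return None
    if t in ("0", "1"):
        return t == "1"
    raise ValueError(f"expected 0, 1 or empty, got {token!r}")


def _parse_float(token: str) -> Optional[float]:
    t = token.strip()
    if t == "":
        return None
    return float(t)


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else ("1" if v else "0")


def _fmt_float(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(float(v))  # shortest exact round-trip representation


def read_cohort(path, delimiter: Optional[str] = None, name: Optional[str] = None) -> Cohort:
    """Read a cohort from a delimited text file.

    Parameters
    ----------
    path : path-like
        File with a header row using the documented column names.
    delimiter : str, optional
        Field delimiter; autodetected between comma and tab when omitted.
    name : str, optional
        Cohort label; defaults to the file stem.

    Raises
    ------
    FormatError
        If a mandatory column is missing.
    RowError
        If a cell cannot be parsed, reporting the 1-based line number.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if delimiter is None:
            delimiter = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
        header = next(csv.reader([first], delimiter=delimiter))
        header = [h.strip() for h in header]
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in COLUMNS}
        subjects = []
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=2):
            if not row or all(cell.strip() == "" for cell in row):
                continue
            if len(row) < len(header):
                raise RowError(lineno, f"expected {len(header)} fields, got {len(row)}")

            def cell(col: str) -> str:
                return row[idx[col]]

            try:
                rec = SubjectRecord(
                    subject_id=cell("subject_id").strip(),
                    sex=Sex.parse(cell("sex")),
                    age=float(cell("age")),
                    total_chol=float(cell("total_chol_mgdl")),
                    hdl_chol=float(cell("hdl_mgdl")),
                    sbp=float(cell("sbp_mmhg")),
                    bp_treated=_parse_bool(cell("bp_treated")),
                    smoker=_parse_bool(cell("smoker")),
                    diabetes=_parse_bool(cell("diabetes")),
                    prev_chf=_parse_bool(cell("prev_chf")),
                    prev_mi=_parse_bool(cell("prev_mi")),
                    prev_stroke=_parse_bool(cell("prev_stroke")),
                    fu_time_ascvd=_parse_float(cell("fu_ascvd_years")),
                    event_ascvd=_parse_bool(cell("event_ascvd")),
                    fu_time_cvdeath=_parse_float(cell("fu_cvdeath_years")),
                    event_cvdeath=_parse_bool(cell("event_cvdeath")),
                )
            except (ValueError, IndexError) as exc:
                if isinstance(exc, RowError):
                    raise
                raise RowError(lineno, str(exc)) from exc
            subjects.append(rec)
    cohort = Cohort(name=name or path.stem, subjects=subjects)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort to delimited text using the documented column set."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(COLUMNS)
        for s in cohort.subjects:
            w.writerow(
                [
                    s.subject_id,
                    s.sex.code,
                    _fmt_float(s.age),
                    _fmt_float(s.total_chol),
                    _fmt_float(s.hdl_chol),
                    _fmt_float(s.sbp),
                    _fmt_bool(s.bp_treated),
                    _fmt_bool(s.smoker),
                    _fmt_bool(s.diabetes),
                    _fmt_bool(s.prev_chf),
                    _fmt_bool(s.prev_mi),
                    _fmt_bool(s.prev_stroke),
                    _fmt_float(s.fu_time_ascvd),
                    _fmt_bool(s.event_ascvd),
                    _fmt_float(s.fu_time_cvdeath),
                    _fmt_bool(s.event_cvdeath),
                ]
            )


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------


def chol_mgdl_to_mmoll(x: float) -> float:
    """Convert total cholesterol from mg/dL to mmol/L (38.67 mg/dL per mmol/L)."""
    if not x > 0 or math.isnan(x):
        raise DomainError(f"cholesterol must be positive, got {x}")
    return x / MGDL_PER_MMOLL


# ---------------------------------------------------------------------------
# exclusions and censoring
# ---------------------------------------------------------------------------


def _exclusion_reason(s: SubjectRecord, cfg: ExclusionConfig) -> Optional[str]:
    if not (cfg.age_min <= s.age <= cfg.age_max):
        return "age"
    flag_map = {"chf": s.prev_chf, "mi": s.prev_mi, "stroke": s.prev_stroke}
    if any(flag_map.get(k) is True for k in cfg.exclude_prevalent):
        return "prevalent_disease"
    missing_endpoint = [
        f for f in cfg.require_complete if f in ENDPOINT_FIELDS and getattr(s, f) is None
    ]
    if missing_endpoint:
        return "missing_endpoint"
    missing_rf = [
        f for f in cfg.require_complete if f not in ENDPOINT_FIELDS and getattr(s, f) is None
    ]
    if missing_rf:
        return "missing_risk_factor"
    return None


def apply_exclusions(cohort: Cohort, cfg: Optional[ExclusionConfig] = None) -> Cohort:
    """Apply eligibility criteria, returning a new cohort with an exclusion log.

    Criteria are checked in the fixed order age, prevalent disease, missing
    endpoint information, missing risk factors; each removed subject is counted
    once under the first criterion that matches, so the log is deterministic
    and its counts sum to the number removed.  Idempotent.
    """
    cfg = cfg or ExclusionConfig()
    log = {k: 0 for k in EXCLUSION_ORDER}
    kept = []
    for s in cohort.subjects:
        reason = _exclusion_reason(s, cfg)
        if reason is None:
            kept.append(s)
        else:
            log[reason] += 1
    return Cohort(name=cohort.name, subjects=kept, exclusion_log=log)


def censor_at_horizon(cohort: Cohort, horizon: float = 10.0,
                      endpoints: Sequence[str] = ("ascvd", "cv_death")) -> Cohort:
    """Administratively censor follow-up at ``horizon`` years.

    Any follow-up time beyond the horizon is truncated to the horizon and the
    corresponding event indicator cleared (an event after the horizon does not
    count).  Times exactly at the horizon are left untouched.
    """
    field_map = {
        "ascvd": ("fu_time_ascvd", "event_ascvd"),
        "cv_death": ("fu_time_cvdeath", "event_cvdeath"),
    }
    out = []
    for s in cohort.subjects:
        changes = {}
        for ep in endpoints:
            fu_f, ev_f = field_map[ep]
            t = getattr(s, fu_f)
            if t is not None and t > horizon:
                changes[fu_f] = float(horizon)
                changes[ev_f] = False
        out.append(replace(s, **changes) if changes else s)
    return Cohort(name=cohort.name, subjects=out, exclusion_log=dict(cohort.exclusion_log))
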