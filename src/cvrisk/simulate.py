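"""Synthetic cohort generation.

Samples covariates matching configurable marginal summaries (age mean/SD,
median and quartiles for lipids and blood pressure, binary prevalences) and
attaches survival outcomes from a configurable true event-generating model,
so the whole analysis pipeline is exercisable without access to study data.

Continuous skewed covariates use log-normal families fitted to the reported
median and interquartile range; event times are exponential within the
10-year window with rate chosen so that P(event <= 10) equals the subject's
true risk exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import yaml
from scipy import stats

from .cohort import Cohort, Sex, SubjectRecord
from .engines import PceEquation, load_default_pce
from .errors import ConfigError

__all__ = [
    "SexBlock",
    "CohortSimConfig",
    "KORA_LIKE",
    "HNR_LIKE",
    "PRESETS",
    "lognormal_from_quartiles",
    "sample_covariates",
    "attach_outcomes",
    "simulate_cohort",
    "load_sim_config",
    "save_sim_config",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6744897...


def lognormal_from_quartiles(median: float, q1: float, q3: float):
    """(mu, sigma) of the log-normal whose median and IQR ratio match.

    mu = ln(median); sigma = ln(q3/q1) / (2 * z_0.75).  Raises ConfigError
    when the quantile spec is not log-normalizable (needs 0 < q1 < median < q3).
    """
    if not (0 < q1 < median < q3):
        raise ConfigError(
            f"quantile spec not log-normalizable: need 0 < q1 < median < q3, "
            f"got ({q1}, {median}, {q3})"
        )
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


@dataclass
class SexBlock:
    """Marginal summaries for one sex."""

    age_mean: float
    age_sd: float
    tc_median: float
    tc_q1: float
    tc_q3: float
    hdl_median: float
    hdl_q1: float
    hdl_q3: float
    sbp_median: float
    sbp_q1: float
    sbp_q3: float
    p_bp_treated: float
    p_smoker: float
    p_diabetes: float

    def validate(self, label: str) -> None:
        for block in ("tc", "hdl", "sbp"):
            q1 = getattr(self, f"{block}_q1")
            med = getattr(self, f"{block}_median")
            q3 = getattr(self, f"{block}_q3")
            if not (0 < q1 < med < q3):
                raise ConfigError(f"{label}.{block}: need 0 < q1 < median < q3")
        for p in ("p_bp_treated", "p_smoker", "p_diabetes"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{label}.{p} must be a probability, got {v}")


@dataclass
class CohortSimConfig:
    """Full simulation recipe; deterministic given ``seed``."""

    name: str
    n: int
    frac_male: float
    male: SexBlock
    female: SexBlock
    fu_mean: float = 8.6
    fu_sd: float = 2.0
    censoring: bool = True
    true_model: str = "pce_true"  # pce_true | pce_scaled | custom_lp
    gamma: float = 1.0            # pce_scaled: true odds = predicted odds / gamma
    theta: Optional[dict] = None  # custom_lp coefficients on named covariates
    h0: float = 0.005             # custom_lp baseline hazard per year
    fatal_fraction: float = 0.35
    seed: int = 0
    age_min: float = 40.0
    age_max: float = 79.0

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigError(f"n must be positive, got {self.n}")
        if not 0.0 <= self.frac_male <= 1.0:
            raise ConfigError("frac_male must be a probability")
        if not 0.0 <= self.fatal_fraction <= 1.0:
            raise ConfigError("fatal_fraction must be a probability")
        if self.true_model not in ("pce_true", "pce_scaled", "custom_lp"):
            raise ConfigError(f"unknown true_model {self.true_model!r}")
        self.male.validate(f"{self.name}.male")
        self.female.validate(f"{self.name}.female")


# Presets emulating two population-based German cohort baselines.
KORA_LIKE = CohortSimConfig(
    name="kora_like",
    n=5238,
    frac_male=0.49,
    male=SexBlock(
        age_mean=56.4, age_sd=9.6,
        tc_median=235, tc_q1=208, tc_q3=263,
        hdl_median=48, hdl_q1=40, hdl_q3=58,
        sbp_median=136, sbp_q1=125, sbp_q3=149,
        p_bp_treated=0.19, p_smoker=0.25, p_diabetes=0.05,
    ),
    female=SexBlock(
        age_mean=55.5, age_sd=9.7,
        tc_median=233, tc_q1=209, tc_q3=264,
        hdl_median=60, hdl_q1=49, hdl_q3=72,
        sbp_median=128, sbp_q1=116, sbp_q3=144,
        p_bp_treated=0.22, p_smoker=0.17, p_diabetes=0.04,
    ),
    fu_mean=8.6,
    fu_sd=2.0,
    fatal_fraction=0.45,
)

HNR_LIKE = CohortSimConfig(
    name="hnr_like",
    n=4208,
    frac_male=0.48,
    male=SexBlock(
        age_mean=58.8, age_sd=7.6,
        tc_median=226, tc_q1=202, tc_q3=249,
        hdl_median=49, hdl_q1=42, hdl_q3=59,
        sbp_median=137, sbp_q1=125, sbp_q3=149,
        p_bp_treated=0.30, p_smoker=0.26, p_diabetes=0.08,
    ),
    female=SexBlock(
        age_mean=59.1, age_sd=7.7,
        tc_median=232, tc_q1=208, tc_q3=260,
        hdl_median=64, hdl_q1=53, hdl_q3=75,
        sbp_median=125, sbp_q1=113, sbp_q3=141,
        p_bp_treated=0.32, p_smoker=0.22, p_diabetes=0.06,
    ),
    fu_mean=9.0,
    fu_sd=2.1,
    fatal_fraction=0.27,
)

PRESETS = {"kora_like": KORA_LIKE, "hnr_like": HNR_LIKE}


# ---------------------------------------------------------------------------
# config file I/O (YAML)
# ---------------------------------------------------------------------------


def save_sim_config(cfg: CohortSimConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def load_sim_config(path) -> CohortSimConfig:
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    try:
        cfg = CohortSimConfig(
            **{**d, "male": SexBlock(**d["male"]), "female": SexBlock(**d["female"])}
        )
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"invalid simulation config {path}: {exc}") from exc
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_covariates(cfg: CohortSimConfig) -> Cohort:
    """Draw a covariate-complete cohort (no outcomes yet), fixed by seed.

    Sex is Bernoulli(frac_male); age is normal truncated to the configured
    window; lipids and blood pressure are log-normal matched to median and
    quartiles; binary covariates are independent Bernoulli draws.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    male = rng.random(n) < cfg.frac_male
    age = np.empty(n)
    tc = np.empty(n)
    hdl = np.empty(n)
    sbp = np.empty(n)
    treated = np.empty(n, dtype=bool)
    smoker = np.empty(n, dtype=bool)
    diabetes = np.empty(n, dtype=bool)
    for is_male, block in ((True, cfg.male), (False, cfg.female)):
        mask = male == is_male
        m = int(mask.sum())
        if m == 0:
            continue
        age[mask] = _truncated_normal(rng, block.age_mean, block.age_sd,
                                      cfg.age_min, cfg.age_max, m)
        for arr, prefix in ((tc, "tc"), (hdl, "hdl"), (sbp, "sbp")):
            mu, sigma = lognormal_from_quartiles(
                getattr(block, f"{prefix}_median"),
                getattr(block, f"{prefix}_q1"),
                getattr(block, f"{prefix}_q3"),
            )
            arr[mask] = rng.lognormal(mean=mu, sigma=sigma, size=m)
        treated[mask] = rng.random(m) < block.p_bp_treated
        smoker[mask] = rng.random(m) < block.p_smoker
        diabetes[mask] = rng.random(m) < block.p_diabetes
    subjects = [
        SubjectRecord(
            subject_id=f"{cfg.name}-{i:06d}",
            sex=Sex.MALE if male[i] else Sex.FEMALE,
            age=float(age[i]),
            total_chol=float(tc[i]),
            hdl_chol=float(hdl[i]),
            sbp=float(sbp[i]),
            bp_treated=bool(treated[i]),
            smoker=bool(smoker[i]),
            diabetes=bool(diabetes[i]),
            prev_chf=False,
            prev_mi=False,
            prev_stroke=False,
        )
        for i in range(n)
    ]
    return Cohort(name=cfg.name, subjects=subjects)


def _true_risks(cohort: Cohort, cfg: CohortSimConfig, pce: PceEquation) -> tuple[np.ndarray, int]:
    """Per-subject true 10-year risk under the configured generating model."""
    if cfg.true_model in ("pce_true", "pce_scaled"):
        p = np.asarray([pce.predict(s).risk10 for s in cohort], dtype=float)
        if cfg.true_model == "pce_scaled" and cfg.gamma != 1.0:
            # gamma is the overestimation factor of the scored equation:
            # true odds = predicted odds / gamma, so gamma > 1 makes the
            # equation overestimate the generated risk.
            odds = p / (1.0 - p) / cfg.gamma
            p = odds / (1.0 + odds)
    else:  # custom_lp
        theta = cfg.theta or {}
        lp = np.zeros(len(cohort))
        for i, s in enumerate(cohort):
            lp[i] = (
                theta.get("age", 0.0) * s.age
                + theta.get("total_chol", 0.0) * s.total_chol
                + theta.get("hdl_chol", 0.0) * s.hdl_chol
                + theta.get("sbp", 0.0) * s.sbp
                + theta.get("smoker", 0.0) * float(s.smoker)
                + theta.get("diabetes", 0.0) * float(s.diabetes)
                + theta.get("male", 0.0) * float(s.sex is Sex.MALE)
            )
        p = 1.0 - np.exp(-cfg.h0 * 10.0 * np.exp(lp))
    eps = 1e-12
    clipped = int(((p <= 0.0) | (p >= 1.0)).sum())
    p = np.clip(p, eps, 1.0 - eps)
    return p, clipped


def attach_outcomes(cohort: Cohort, cfg: CohortSimConfig,
                    pce: Optional[PceEquation] = None) -> Cohort:
    """Attach survival outcomes to a covariate cohort.

    Event times are exponential with rate ``-ln(1 - p_i) / 10`` so the event
    probability by year 10 equals the true risk exactly; censoring times are
    normal (``fu_mean``, ``fu_sd``) truncated to positive values, or absent
    when ``cfg.censoring`` is false.  A ``fatal_fraction`` share of events is
    additionally flagged as cardiovascular death at the same time.
    """
    cfg.validate()
    pce = pce or load_default_pce()
    # independent stream so covariate draws are untouched by outcome draws
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 1)))
    n = len(cohort)
    p, n_clipped = _true_risks(cohort, cfg, pce)
    if n_clipped:
        import warnings

        warnings.warn(f"{n_clipped} true risks clipped into (0,1)", stacklevel=2)
    rate = -np.log1p(-p) / 10.0
    t_event = rng.exponential(scale=1.0, size=n) / rate
    if cfg.censoring:
        t_cens = _truncated_normal(rng, cfg.fu_mean, cfg.fu_sd, 0.0, np.inf, n)
    else:
        t_cens = np.full(n, np.inf)
    horizon = 10.0
    t_obs = np.minimum.reduce([t_event, t_cens, np.full(n, horizon)])
    event = t_event <= np.minimum(t_cens, horizon)
    fatal = event & (rng.random(n) < cfg.fatal_fraction)
    subjects = []
    for i, s in enumerate(cohort):
        subjects.append(
            replace(
                s,
                fu_time_ascvd=float(t_obs[i]),
                event_ascvd=bool(event[i]),
                fu_time_cvdeath=float(t_obs[i]),
                event_cvdeath=bool(fatal[i]),
            )
        )
    return Cohort(name=cohort.name, subjects=subjects, exclusion_log=dict(cohort.exclusion_log))


def simulate_cohort(cfg: CohortSimConfig, pce: Optional[PceEquation] = None) -> Cohort:
    """Sample covariates and outcomes in one deterministic step."""
    return attach_outcomes(sample_covariates(cfg), cfg, pce=pce)
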