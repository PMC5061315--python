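import dataclasses

import numpy as np
import pytest

from cvrisk.cohort import Cohort, Sex, SubjectRecord


def make_subject(
    subject_id="s1",
    sex=Sex.MALE,
    age=55.0,
    total_chol=213.0,
    hdl_chol=50.0,
    sbp=120.0,
    bp_treated=False,
    smoker=False,
    diabetes=False,
    **kw,
):
    return SubjectRecord(
        subject_id=subject_id,
        sex=sex,
        age=age,
        total_chol=total_chol,
        hdl_chol=hdl_chol,
        sbp=sbp,
        bp_treated=bp_treated,
        smoker=smoker,
        diabetes=diabetes,
        **kw,
    )


def make_cohort(n, n_events=0, name="toy", seed=0, fu=8.0):
    """Complete-field cohort with the first ``n_events`` subjects as events."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        subjects.append(
            make_subject(
                subject_id=f"{name}-{i}",
                sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                age=float(rng.uniform(40, 79)),
                total_chol=float(rng.uniform(150, 300)),
                hdl_chol=float(rng.uniform(30, 90)),
                sbp=float(rng.uniform(100, 180)),
                smoker=bool(rng.random() < 0.3),
                fu_time_ascvd=float(fu),
                event_ascvd=i < n_events,
                fu_time_cvdeath=float(fu),
                event_cvdeath=False,
            )
        )
    return Cohort(name=name, subjects=subjects)


@pytest.fixture
def reference_male():
    return make_subject("ref-m", Sex.MALE)


@pytest.fixture
def reference_female():
    return make_subject("ref-f", Sex.FEMALE)


@pytest.fixture
def toy_cohort():
    return make_cohort(20, n_events=5, seed=42)
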