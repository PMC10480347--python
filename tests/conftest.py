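"""Shared fixtures: small synthetic cohorts and fitted models reused across
test modules (session-scoped where fitting is expensive)."""

import numpy as np
import pandas as pd
import pytest

from trajprs import datagen as dg
from trajprs import lgmm


@pytest.fixture(scope="session")
def small_cfg() -> dg.GeneratorConfig:
    """A 600-subject default-structure cohort configuration."""
    return dg.GeneratorConfig(n_subjects=600, seed=20260901)


@pytest.fixture(scope="session")
def small_cohort_long(small_cfg):
    return dg.generate(small_cfg)


@pytest.fixture(scope="session")
def two_class_fixture():
    """Well-separated two-class linear trajectories with known parameters."""
    cfg = dg.GeneratorConfig(
        n_subjects=300,
        class_shares=(0.6, 0.4),
        class_intercepts=(10.0, 50.0),
        class_slopes=(-0.5, 2.0),
        prs_class_logor=np.zeros((6, 1)),
        covariate_class_logor=np.zeros((10, 1)),
        target_complete_share=1.0,
        unit_nonresponse_rate=0.0,
        seed=7,
    )
    cohort, long = dg.generate(cfg)
    return cfg, cohort, long


@pytest.fixture(scope="session")
def two_class_fit(two_class_fixture):
    cfg, cohort, long = two_class_fixture
    spec = lgmm.LGMMSpec(n_classes=2, multistart=(3, 30), seed=5)
    return lgmm.fit_lgmm(long, cohort, spec), cohort, long


@pytest.fixture(scope="session")
def four_class_fit(small_cohort_long):
    cohort, long = small_cohort_long
    spec = lgmm.LGMMSpec(n_classes=4, multistart=(3, 30), seed=5)
    return lgmm.fit_lgmm(long, cohort, spec), cohort, long
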