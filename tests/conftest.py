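import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import bioage as ba

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with all default imperfections (missingness,
    outliers, subgroups) for filter and pipeline tests."""
    cfg = ba.SimConfig(n_per_stratum=25, seed=11)
    cohort, truth = ba.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def clean_cfg():
    """Ten informative markers, no missingness/outliers/covariate effects:
    the cleanest setting in which model algebra can be checked."""
    return ba.SimConfig(
        n_per_stratum=40,
        panel_spec=ba.default_panel()[:10],
        external_spec=[],
        subgroup_fractions={},
        hormone_use_rate=0.0,
        smoker_rate=0.0,
        missing_rate=0.0,
        outlier_rate=0.0,
        seed=202,
    )


@pytest.fixture(scope="session")
def fitted(clean_cfg):
    """(train, model, scored_train) for female subjects of the clean cohort."""
    cohort, _ = ba.generate_cohort(clean_cfg)
    train = cohort[cohort["sex"] == "F"]
    panel = train[clean_cfg.panel_names]
    model = ba.fit_model(panel, train["age"], sex="F")
    scored = ba.apply_model(model, train)
    return train, model, scored
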