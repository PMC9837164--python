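import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from facepls.simulate import CohortSpec, EffectSpec, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


TINY_SPEC = CohortSpec(
    n_subjects=4,
    n_men=2,
    n_women=2,
    trial_seconds=6.0,
    fps=25.0,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but design-complete cohort: 4 subjects x 3 conditions x 3 trials."""
    return generate_cohort(TINY_SPEC, EffectSpec())


@pytest.fixture(scope="session")
def tiny_cohort_dir(tiny_cohort, tmp_path_factory):
    """The tiny cohort written to disk (CSV tracks + annotations + truth)."""
    d = tmp_path_factory.mktemp("cohort")
    tiny_cohort.write(d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
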