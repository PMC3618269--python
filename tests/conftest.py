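import numpy as np
import pytest

import countybp as cb


@pytest.fixture(scope="session")
def small_world():
    cfg = cb.WorldConfig(
        n_counties=16, n_states=4, years=(2001, 2005, 2009), seed=11
    )
    return cb.generate_world(cfg)


@pytest.fixture(scope="session")
def exam_20k(small_world):
    return cb.sample_exam_survey(small_world, 20_000, seed=101)


@pytest.fixture(scope="session")
def stage1_fits(small_world, exam_20k):
    specs = cb.default_spec_set(small_world.config.waves)
    return cb.fit_bias_models(exam_20k, specs)


@pytest.fixture(scope="session")
def phone_sample(small_world):
    return cb.sample_phone_survey(small_world, 100, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
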