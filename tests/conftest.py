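import pytest

import genomethate as g


@pytest.fixture(scope="session")
def spec():
    return g.default_spec(base_seed=7)


@pytest.fixture(scope="session")
def small_cohort(spec):
    return g.gen_cohort(spec, g.CohortConfig(n_subjects=80, seed=42))


@pytest.fixture(scope="session")
def small_run(small_cohort, spec):
    return g.prepare_run(small_cohort, spec)
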