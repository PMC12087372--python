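import numpy as np
import pytest

from wmhcentiles import normative_model as nm
from wmhcentiles import synthetic_data as sd


@pytest.fixture(scope="session")
def gen_params():
    return sd.GenerativeParams()


@pytest.fixture(scope="session")
def toy_atlas():
    return sd.generate_toy_atlas((20, 20, 20), n_tracts=3, seed=7)


@pytest.fixture(scope="session")
def small_cohort(gen_params):
    """~600 subjects across staggered age ranges; enough for stable fits."""
    specs = sd.default_study_cohorts(600)
    return sd.generate_cohort(specs, gen_params, seed=11)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return [
        nm.SubjectRecord(s.id, s.age, s.sex, s.true_total_log10,
                         history_of_stroke=s.history_of_stroke)
        for s in small_cohort
    ]


def make_linear_records(n, sex="female", slope=0.03, intercept=-1.5,
                        noise=0.3, seed=0, age_range=(40, 90)):
    """Records with an exactly linear conditional quantile surface."""
    rng = np.random.default_rng(seed)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n)
    y = intercept + slope * ages + rng.normal(0, noise, size=n)
    return [
        nm.SubjectRecord(f"s{i}", int(a), sex, float(v))
        for i, (a, v) in enumerate(zip(ages, y))
    ]
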