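import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metabconsensus import CohortConfig, generate_cohort
from metabconsensus.dataset import MetabolomicsDataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-design cohort: 40 + 40 samples, 206 metabolites."""
    return generate_cohort(CohortConfig(seed=1))


def make_dataset(values, labels, names=None, panel=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"m{j}" for j in range(values.shape[1])]
    return MetabolomicsDataset(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        labels=np.asarray(labels, dtype=int),
        metabolite_names=list(names),
        values=values,
        panel=panel,
    )


@pytest.fixture
def toy_dataset():
    """4 samples × 3 metabolites, complete, two per class."""
    rng = np.random.default_rng(0)
    return make_dataset(rng.lognormal(1.0, 0.3, (4, 3)), [1, 1, 0, 0])
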