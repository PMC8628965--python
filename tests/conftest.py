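import numpy as np
import pytest

from diffshape import Condition, ReplicateSet, aggregate, filter_outliers
from diffshape.synth import GeneratorConfig, make_structure, simulate_reactivities


@pytest.fixture(scope="session")
def ann188():
    return make_structure(seed=0, length=188)


@pytest.fixture()
def default_cfg():
    return GeneratorConfig(seed=0)


def make_replicate_set(values_per_position, bases=None, condition=None, start=1):
    """Build a ReplicateSet from a list of per-position value tuples."""
    n = len(values_per_position)
    return ReplicateSet(
        condition=condition or Condition(),
        positions=np.arange(start, start + n),
        bases=np.array(bases or ["A"] * n, dtype="U1"),
        values=[np.array(v, dtype=float) for v in values_per_position],
    )


@pytest.fixture(scope="session")
def temperature_profiles(ann188):
    """Aggregated 1M7 profiles across the five-temperature ladder (seed 0)."""
    cfg = GeneratorConfig(seed=0)
    profiles = []
    for temp in (37.0, 53.0, 65.0, 74.0, 85.0):
        cond = Condition(probe="1M7", mg_mM=5.0, temperature_C=temp)
        profiles.append(aggregate(filter_outliers(simulate_reactivities(ann188, cond, cfg))))
    return profiles
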