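import numpy as np
import pytest

from eaccd import FactorScheme, SurvivalRecord


@pytest.fixture
def two_level_scheme():
    return FactorScheme(factor_names=("F",), levels_per_factor=(("X", "Y"),))


@pytest.fixture
def three_factor_scheme():
    return FactorScheme(
        factor_names=("A", "B", "C"),
        levels_per_factor=(("a1", "a2"), ("b1", "b2"), ("c1", "c2")),
    )


def make_records(times, events, level_tuples=None):
    if level_tuples is None:
        level_tuples = [()] * len(times)
    return [
        SurvivalRecord(time=float(t), event=int(e), levels=tuple(l))
        for t, e, l in zip(times, events, level_tuples)
    ]


@pytest.fixture
def exponential_pair():
    """Two exponential samples with true hazard ratio 2, no censoring."""
    rng = np.random.default_rng(2024)
    a = (rng.exponential(1.0, 5000), np.ones(5000, dtype=int))
    b = (rng.exponential(0.5, 5000), np.ones(5000, dtype=int))
    return a, b
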