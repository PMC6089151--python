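"""Shared independent oracles and small utilities for the test suite.

Everything here is deliberately naive (exhaustive enumeration, O(n^2)
loops) so that it stays independent of the implementation paths it checks.
"""

import itertools

import numpy as np


def brute_concordance(times, events, risks) -> float:
    """All-pairs Harrell C: comparable iff t_i < t_j and event_i == 1."""
    concordant = 0.0
    comparable = 0
    n = len(times)
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if i == j or not times[i] < times[j]:
                continue
            comparable += 1
            if risks[i] > risks[j]:
                concordant += 1.0
            elif risks[i] == risks[j]:
                concordant += 0.5
    if comparable == 0:
        raise ZeroDivisionError("no comparable pairs")
    return concordant / comparable


def exhaustive_medoid_cost(D: np.ndarray, k: int) -> float:
    """Global optimum of the k-medoid objective by full enumeration."""
    n = D.shape[0]
    return min(
        float(D[:, list(meds)].min(axis=1).sum())
        for meds in itertools.combinations(range(n), k)
    )


def random_dissimilarity(rng: np.random.Generator, n: int, low=0.1, high=10.0) -> np.ndarray:
    A = rng.uniform(low, high, (n, n))
    D = (A + A.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def random_initial_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Hazard-ratio-style matrix: exp of |log-hazard difference| plus jitter."""
    b = rng.normal(0.0, 1.0, n)
    L = np.abs(b[:, None] - b[None, :]) + rng.normal(0.0, 0.05, (n, n))
    L = np.abs(L + L.T) / 2.0
    D = np.exp(L)
    np.fill_diagonal(D, 0.0)
    return D


def partitions_equal(a, b) -> bool:
    """True iff two label vectors induce the same partition."""
    fwd, rev = {}, {}
    for x, y in zip(a, b):
        if fwd.setdefault(x, y) != y or rev.setdefault(y, x) != x:
            return False
    return True


def grouping_partition(labels, group_of):
    """Frozenset-of-frozensets view of a grouping over labels."""
    groups = {}
    for lab, g in zip(labels, group_of):
        groups.setdefault(g, set()).add(lab)
    return frozenset(frozenset(v) for v in groups.values())
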