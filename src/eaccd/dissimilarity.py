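"""Dissimilarities between combinations: hazard-ratio based and ensemble-learned.

Two stages:

1. *Initial* dissimilarity between two combinations is the larger of the
   two reciprocal Cox hazard ratios between them (an effect size, always
   >= 1 off the diagonal).
2. *Learned* dissimilarity is produced by an ensemble of PAM (Partitioning
   Around Medoids) runs on the initial matrix: for every cluster count
   k = 1..n, PAM partitions the combinations, and the learned dissimilarity
   of a pair is the fraction of the n partitions that separate them.
   Values therefore lie in [1/n, (n-1)/n]: k=1 never separates a pair,
   k=n always does.

The PAM implementation is the classical 2-phase BUILD/SWAP algorithm on an
arbitrary dissimilarity matrix with fully deterministic lowest-index tie
breaking, which makes the learned matrix a pure function of the initial
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .combinations import CombinationDataset
from .exceptions import EaccdError, NoEventsError
from .survival import hazard_ratio

logger = logging.getLogger(__name__)

_KINDS = ("initial", "learned")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric nonnegative matrix over combination labels, zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if self.kind not in _KINDS:
            raise EaccdError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if v.shape != (n, n):
            raise EaccdError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise EaccdError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise EaccdError("dissimilarity matrix must have a zero diagonal")
        off = v[~np.eye(n, dtype=bool)]
        if off.size and off.min() < 0:
            raise EaccdError("dissimilarities must be nonnegative")
        if self.kind == "initial" and off.size and off.min() < 1 - 1e-9:
            raise EaccdError("initial dissimilarities must be >= 1 off the diagonal")
        if self.kind == "learned" and off.size:
            lo, hi = 1.0 / n, (n - 1.0) / n
            if off.min() < lo - 1e-9 or off.max() > hi + 1e-9:
                raise EaccdError(
                    f"learned dissimilarities must lie in [{lo:.4g}, {hi:.4g}]"
                )

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_csv(self, path: str | Path) -> None:
        """Write a labelled delimited matrix (cache for expensive Cox fits)."""
        df = pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise EaccdError("row and column labels differ in matrix file")
        return cls(labels=tuple(str(x) for x in df.index), values=df.to_numpy(float), kind=kind)


def initial_dissimilarity_matrix(dataset: CombinationDataset) -> DissimilarityMatrix:
    """Pairwise hazard-ratio dissimilarities: entry (i, j) = max(HR, 1/HR).

    Each unordered pair is fitted once; the diagonal is 0 (PAM and linkage
    need zero self-dissimilarity even though a self hazard ratio is 1).

    Raises
    ------
    EaccdError
        If fewer than 2 combinations are present, or a pair has no pooled
        events (the offending pair is named).
    """
    n = dataset.n
    if n < 2:
        raise EaccdError("need at least 2 combinations")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = hazard_ratio(dataset.arrays(i), dataset.arrays(j))
            except NoEventsError as err:
                raise EaccdError(
                    f"no events pooled for pair ({dataset.labels[i]}, {dataset.labels[j]})"
                ) from err
            if not est.converged:
                logger.warning(
                    "initial_dissimilarity: non-converged fit for pair (%s, %s); "
                    "using capped estimate",
                    dataset.labels[i], dataset.labels[j],
                )
            d = max(est.hr, 1.0 / est.hr)
            values[i, j] = values[j, i] = d
    return DissimilarityMatrix(labels=dataset.labels, values=values, kind="initial")


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartitionLabels:
    """A PAM partition: cluster assignment, medoids and total cost."""

    assignment: np.ndarray  # cluster index per item, 0..k-1
    k: int
    medoids: tuple[int, ...]  # sorted item indices
    cost: float


def _as_matrix(d) -> np.ndarray:
    return d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, float)


def pam_partition(d, k: int) -> PartitionLabels:
    """2-phase PAM (BUILD then steepest-descent SWAP) with deterministic ties.

    All ties -- BUILD candidates, nearest-medoid assignment, equally good
    swaps -- break toward the lowest index, so the result is a pure function
    of the matrix.

    BUILD seeds the first medoid with the minimiser of total dissimilarity
    and each further medoid with the largest cost reduction; SWAP repeatedly
    applies the single (medoid, non-medoid) exchange with the largest cost
    decrease until none improves.
    """
    D = _as_matrix(d)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise EaccdError(f"k must be in [1, {n}], got {k}")

    if k == n:
        return PartitionLabels(
            assignment=np.arange(n), k=k, medoids=tuple(range(n)), cost=0.0
        )

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dist_to_med = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dist_to_med[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        chosen = int(np.argmax(gains))
        medoids.append(chosen)
        dist_to_med = np.minimum(dist_to_med, D[chosen])
    medoids.sort()

    def total_cost(meds: Sequence[int]) -> float:
        return float(D[:, list(meds)].min(axis=1).sum())

    cost = total_cost(medoids)

    # SWAP (steepest descent)
    while True:
        best_delta = -1e-12
        best_swap = None
        med_set = set(medoids)
        non_medoids = [h for h in range(n) if h not in med_set]
        for m in medoids:
            rest = [x for x in medoids if x != m]
            base = D[:, rest].min(axis=1) if rest else np.full(n, np.inf)
            new_costs = np.minimum(base[:, None], D[:, non_medoids]).sum(axis=0)
            for pos, h in enumerate(non_medoids):
                delta = float(new_costs[pos]) - cost
                if delta < best_delta:
                    best_delta = delta
                    best_swap = (m, h)
        if best_swap is None:
            break
        m, h = best_swap
        medoids = sorted(x for x in medoids if x != m) + [h]
        medoids.sort()
        cost = total_cost(medoids)

    med_arr = np.array(medoids)
    assignment = np.argmin(D[:, med_arr], axis=1)  # first occurrence = lowest medoid
    cost = float(D[np.arange(n), med_arr[assignment]].sum())
    return PartitionLabels(
        assignment=assignment, k=k, medoids=tuple(medoids), cost=cost
    )


def learned_dissimilarity_matrix(d0: DissimilarityMatrix) -> DissimilarityMatrix:
    """Ensemble co-separation frequencies over PAM partitions for k = 1..n.

    learned(i, j) = (1/n) * #{k : PAM_k separates i and j}.  Deterministic
    given ``d0`` because PAM's tie rules are deterministic.  k = 1 and k = n
    are included exactly as the ensemble definition states, which pins the
    off-diagonal range to [1/n, (n-1)/n].
    """
    if d0.kind != "initial":
        raise EaccdError("learned dissimilarities are computed from an initial matrix")
    n = d0.n
    if n < 2:
        raise EaccdError("need at least 2 combinations")
    separations = np.zeros((n, n))
    for k in range(1, n + 1):
        labels = pam_partition(d0, k).assignment
        separations += labels[:, None] != labels[None, :]
    values = separations / n
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(labels=d0.labels, values=values, kind="learned")
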