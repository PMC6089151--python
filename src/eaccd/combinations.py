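"""Factor-level combinations: the unit of analysis.

A *combination* is the subset of patients sharing one level of every
selected prognostic factor (e.g. ``T1N0M0``).  Combinations with too few
patients are excluded by a minimum-case filter so that the downstream
hazard-ratio fits rest on a sufficient number of patients and deaths.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EaccdError
from .survival import SurvivalRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactorScheme:
    """Named categorical prognostic factors and their admissible levels."""

    factor_names: tuple[str, ...]
    levels_per_factor: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        if len(self.factor_names) != len(self.levels_per_factor):
            raise EaccdError("factor_names and levels_per_factor lengths differ")
        if len(set(self.factor_names)) != len(self.factor_names):
            raise EaccdError("factor names must be unique")
        for name, levels in zip(self.factor_names, self.levels_per_factor):
            if len(levels) < 1:
                raise EaccdError(f"factor {name!r} has no levels")
            if len(set(levels)) != len(levels):
                raise EaccdError(f"factor {name!r} has duplicate levels")

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def label_of(self, levels: Sequence[str]) -> str:
        """Concatenated level string in factor order (e.g. ``T1N0M0``)."""
        return "".join(levels)

    def is_valid(self, levels: Sequence[str]) -> bool:
        if len(levels) != self.n_factors:
            return False
        return all(
            lev in allowed for lev, allowed in zip(levels, self.levels_per_factor)
        )

    def all_level_tuples(self) -> list[tuple[str, ...]]:
        return [tuple(t) for t in itertools.product(*self.levels_per_factor)]

    def subset(self, names: Sequence[str]) -> "FactorScheme":
        """Scheme restricted to the given factor names (original order kept)."""
        missing = [n for n in names if n not in self.factor_names]
        if missing:
            raise EaccdError(f"unknown factors: {missing}")
        keep = [n for n in self.factor_names if n in set(names)]
        idx = [self.factor_names.index(n) for n in keep]
        return FactorScheme(
            factor_names=tuple(keep),
            levels_per_factor=tuple(self.levels_per_factor[i] for i in idx),
        )


@dataclass(frozen=True)
class Combination:
    id: int
    label: str
    levels: tuple[str, ...]


class CombinationDataset:
    """Patients partitioned into retained factor-level combinations.

    Combination ids are assigned by lexicographic order of level tuples, so
    the partition is independent of input row order.  Patient-level arrays
    (``patient_times``, ``patient_events``, ``patient_combo``) are kept
    alongside the per-combination record lists for fast concordance
    computations.
    """

    def __init__(
        self,
        scheme: FactorScheme,
        combinations: Sequence[Combination],
        members: Sequence[Sequence[SurvivalRecord]],
        min_cases: int,
        dropped: Sequence[tuple[str, int]] = (),
        n_invalid: int = 0,
    ):
        if len(combinations) != len(members):
            raise EaccdError("combinations and members lengths differ")
        self.scheme = scheme
        self.combinations = tuple(combinations)
        self.members = tuple(tuple(m) for m in members)
        self.min_cases = int(min_cases)
        self.dropped = tuple(dropped)
        self.n_invalid = int(n_invalid)

        self._times = [
            np.fromiter((r.time for r in m), dtype=float, count=len(m))
            for m in self.members
        ]
        self._events = [
            np.fromiter((r.event for r in m), dtype=np.int64, count=len(m))
            for m in self.members
        ]
        sizes = [len(m) for m in self.members]
        self.patient_times = (
            np.concatenate(self._times) if sizes else np.empty(0)
        )
        self.patient_events = (
            np.concatenate(self._events) if sizes else np.empty(0, dtype=np.int64)
        )
        self.patient_combo = np.repeat(np.arange(len(sizes)), sizes)

    @property
    def n(self) -> int:
        return len(self.combinations)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.combinations)

    @property
    def n_patients(self) -> int:
        return int(self.patient_times.size)

    def index_of(self, label: str) -> int:
        for c in self.combinations:
            if c.label == label:
                return c.id
        raise EaccdError(f"unknown combination label {label!r}")

    def times(self, i: int) -> np.ndarray:
        return self._times[i]

    def events(self, i: int) -> np.ndarray:
        return self._events[i]

    def arrays(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(times, events) pair for combination ``i``."""
        return self._times[i], self._events[i]


def build_combinations(
    records: Iterable[SurvivalRecord],
    scheme: FactorScheme,
    min_cases: int = 100,
) -> CombinationDataset:
    """Partition records by exact level tuple and apply the size filter.

    Records with a missing or unrecognised level are excluded (with a
    logged count).  Retained combinations must have at least ``min_cases``
    records and at least one observed event; everything excluded by either
    rule is reported in ``dropped``.

    Raises
    ------
    EaccdError
        If no records are given, or fewer than 2 combinations survive the
        filter (pairwise dissimilarities would be impossible).
    """
    if min_cases < 1:
        raise EaccdError(f"min_cases must be >= 1, got {min_cases}")
    records = list(records)
    if not records:
        raise EaccdError("no input records")

    groups: dict[tuple[str, ...], list[SurvivalRecord]] = {}
    n_invalid = 0
    for r in records:
        if not scheme.is_valid(r.levels):
            n_invalid += 1
            continue
        groups.setdefault(tuple(r.levels), []).append(r)
    if n_invalid:
        logger.info("build_combinations: %d records with missing/invalid levels dropped", n_invalid)

    retained: list[tuple[tuple[str, ...], list[SurvivalRecord]]] = []
    dropped: list[tuple[str, int]] = []
    for levels in sorted(groups):
        members = groups[levels]
        label = scheme.label_of(levels)
        if len(members) < min_cases:
            dropped.append((label, len(members)))
        elif not any(r.event == 1 for r in members):
            # Hazard ratios are unidentifiable without events; excluded.
            logger.warning(
                "build_combinations: combination %s has %d cases but no events; dropped",
                label, len(members),
            )
            dropped.append((label, len(members)))
        else:
            retained.append((levels, members))

    if len(retained) == 0:
        raise EaccdError("no combination satisfies the minimum-case filter")
    if len(retained) < 2:
        raise EaccdError(
            "fewer than 2 combinations retained; pairwise dissimilarities impossible"
        )

    combos = [
        Combination(id=i, label=scheme.label_of(levels), levels=levels)
        for i, (levels, _) in enumerate(retained)
    ]
    members = [m for _, m in retained]
    return CombinationDataset(
        scheme=scheme,
        combinations=combos,
        members=members,
        min_cases=min_cases,
        dropped=dropped,
        n_invalid=n_invalid,
    )


def project_factors(
    records: Iterable[SurvivalRecord],
    scheme: FactorScheme,
    keep: Sequence[str],
) -> tuple[list[SurvivalRecord], FactorScheme]:
    """Project records onto a subset of factors (for coarser systems).

    Useful for head-to-head comparisons of systems built on nested factor
    sets over the same patients.
    """
    sub = scheme.subset(keep)
    idx = [scheme.factor_names.index(n) for n in sub.factor_names]
    projected = [
        SurvivalRecord(
            time=r.time,
            event=r.event,
            levels=tuple(r.levels[i] for i in idx),
        )
        for r in records
    ]
    return projected, sub
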