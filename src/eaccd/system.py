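"""Prognostic-system assembly: C-index per cut, n* selection, KM summaries.

A prognostic system is the four-part deliverable: the dendrogram, the
C-index of the selected cut, the group assignment, and the per-group
Kaplan-Meier curves.  The cut is chosen as n*, the smallest number of
groups whose C-index is within a plateau tolerance of the curve maximum
(tolerance 0 reproduces the strict "minimum k attaining the maximum"
rule); a forced k can be supplied to mirror externally motivated choices.

Each group's risk score is the negative of its KM restricted mean survival
time over a horizon (ties broken by 5-year survival); patients inherit
their group's score, and Harrell's C over all patients scores the cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

from .combinations import CombinationDataset, FactorScheme, build_combinations
from .dendrogram import Dendrogram, GroupAssignment, complete_linkage, cut_dendrogram
from .dissimilarity import (
    initial_dissimilarity_matrix,
    learned_dissimilarity_matrix,
)
from .exceptions import EaccdError, PipelineError
from .survival import KMCurve, SurvivalRecord, harrell_c, km_estimate

logger = logging.getLogger(__name__)

#: Time (in the dataset's units, months by convention) at which survival is
#: read off to break restricted-mean ties between groups.
TIE_BREAK_TIME = 60.0


@dataclass(frozen=True)
class CIndexCurve:
    """C-index of the dendrogram cut at every k = 1..n."""

    ks: tuple[int, ...]
    values: tuple[float, ...]

    def value_at(self, k: int) -> float:
        return self.values[self.ks.index(k)]

    @property
    def max_value(self) -> float:
        return max(self.values)


@dataclass(frozen=True)
class CutSelection:
    n_star: int
    c_max: float
    tolerance: float
    forced: bool = False


@dataclass(frozen=True)
class BuildConfig:
    """Knobs of the pipeline.

    ``horizon`` defaults to the largest observed event time; ``tolerance``
    is the C-index plateau tolerance for n* selection (0 = strict rule);
    ``force_k`` overrides selection entirely.
    """

    min_cases: int = 100
    horizon: float | None = None
    tolerance: float = 0.0
    force_k: int | None = None


@dataclass(frozen=True)
class PrognosticSystem:
    """Dendrogram + selected cut + group assignment + C-index + KM curves.

    Group numbering is by increasing risk: group 1 (index 0) has the best
    survival.  ``km_per_group`` is in that order.
    """

    labels: tuple[str, ...]
    dendrogram: Dendrogram
    curve: CIndexCurve
    selection: CutSelection
    groups: GroupAssignment
    c_index: float
    km_per_group: tuple[KMCurve, ...]
    config: BuildConfig
    horizon: float
    dropped: tuple[tuple[str, int], ...] = ()

    def group_table(self) -> list[tuple[str, int]]:
        """(combination label, 1-based group number) rows, best survival first."""
        rows = [
            (label, g + 1) for label, g in zip(self.labels, self.groups.group_of)
        ]
        return sorted(rows, key=lambda r: (r[1], r[0]))


def group_risk_scores(
    dataset: CombinationDataset, groups: GroupAssignment, horizon: float
) -> np.ndarray:
    """Ordinal risk score per group from restricted mean survival time.

    Each group is ranked by the negative of its pooled KM restricted mean
    over [0, horizon]; rank 0 = best survival.  Ties in the restricted mean
    break by 5-year KM survival; groups tied on both (e.g. identical
    member sets) share a rank, so their patients remain risk-tied for the
    concordance index.
    """
    if not horizon > 0:
        raise EaccdError(f"horizon must be positive, got {horizon!r}")
    group_of = np.asarray(groups.group_of)
    if group_of.size != dataset.n:
        raise EaccdError("group assignment does not match dataset combinations")
    k = groups.k
    keys = []
    for g in range(k):
        members = np.flatnonzero(group_of == g)
        if members.size == 0:
            raise EaccdError(f"group {g} is empty")
        times = np.concatenate([dataset.times(i) for i in members])
        events = np.concatenate([dataset.events(i) for i in members])
        km = km_estimate((times, events))
        keys.append((-km.restricted_mean(horizon), -km.survival_at(TIE_BREAK_TIME)))

    order = sorted(range(k), key=lambda g: keys[g])
    scores = np.empty(k)
    rank = -1
    prev = None
    for g in order:
        if keys[g] != prev:
            rank += 1
            prev = keys[g]
        scores[g] = rank
    return scores


def c_index_of_grouping(
    dataset: CombinationDataset, groups: GroupAssignment, horizon: float
) -> float:
    """Harrell's C over all patients, each carrying its group's risk score."""
    scores = group_risk_scores(dataset, groups, horizon)
    group_of = np.asarray(groups.group_of)
    risk = scores[group_of[dataset.patient_combo]]
    return harrell_c(dataset.patient_times, dataset.patient_events, risk)


def c_index_curve(
    dataset: CombinationDataset, tree: Dendrogram, horizon: float
) -> CIndexCurve:
    """C-index of the cut at every k = 1..n."""
    if set(tree.leaves) != set(dataset.labels) or tree.leaves != dataset.labels:
        raise EaccdError("dendrogram leaves do not match dataset combination labels")
    ks = tuple(range(1, dataset.n + 1))
    values = tuple(
        c_index_of_grouping(dataset, cut_dendrogram(tree, k), horizon) for k in ks
    )
    return CIndexCurve(ks=ks, values=values)


def select_nstar(curve: CIndexCurve, tolerance: float = 0.0) -> CutSelection:
    """Smallest k whose C-index is within ``tolerance`` of the maximum."""
    if not curve.ks:
        raise EaccdError("empty C-index curve")
    if tolerance < 0:
        raise EaccdError("tolerance must be nonnegative")
    c_max = curve.max_value
    for k, v in zip(curve.ks, curve.values):
        if v >= c_max - tolerance:
            return CutSelection(n_star=k, c_max=c_max, tolerance=tolerance)
    raise AssertionError("unreachable: the maximiser satisfies the bound")


def _risk_ordered_groups(
    dataset: CombinationDataset, raw: GroupAssignment, horizon: float
) -> tuple[GroupAssignment, np.ndarray]:
    """Renumber groups so index 0 = best survival (ties by smallest label)."""
    scores = group_risk_scores(dataset, raw, horizon)
    group_of = np.asarray(raw.group_of)
    labels = dataset.labels

    def smallest_label(g: int) -> str:
        return min(labels[i] for i in np.flatnonzero(group_of == g))

    order = sorted(range(raw.k), key=lambda g: (scores[g], smallest_label(g)))
    remap = {old: new for new, old in enumerate(order)}
    new_group_of = tuple(remap[g] for g in raw.group_of)
    new_scores = scores[order]
    assignment = GroupAssignment(
        k=raw.k, group_of=new_group_of, ordered_groups=tuple(range(raw.k))
    )
    return assignment, new_scores


def _default_horizon(dataset: CombinationDataset) -> float:
    event_times = dataset.patient_times[dataset.patient_events == 1]
    if event_times.size == 0:
        raise EaccdError("no observed events; cannot set a horizon")
    return float(event_times.max())


def build_prognostic_system(
    records: Iterable[SurvivalRecord],
    scheme: FactorScheme,
    config: BuildConfig = BuildConfig(),
) -> PrognosticSystem:
    """Run the full pipeline: combinations -> dissimilarities -> dendrogram
    -> C-index curve -> cut selection -> KM summaries.

    Deterministic given inputs and config.  Failures carry the name of the
    stage that raised them.
    """

    def stage(name: str, fn: Callable, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except EaccdError as err:
            raise PipelineError(name, str(err)) from err

    dataset = stage("combinations", build_combinations, records, scheme, config.min_cases)
    d0 = stage("initial_dissimilarity", initial_dissimilarity_matrix, dataset)
    learned = stage("learned_dissimilarity", learned_dissimilarity_matrix, d0)
    tree = stage("dendrogram", complete_linkage, learned)
    horizon = config.horizon if config.horizon is not None else _default_horizon(dataset)
    if not horizon > 0:
        raise PipelineError("configuration", f"horizon must be positive, got {horizon!r}")
    curve = stage("c_index_curve", c_index_curve, dataset, tree, horizon)

    if config.force_k is not None:
        if not 1 <= config.force_k <= dataset.n:
            raise PipelineError(
                "selection", f"forced k={config.force_k} outside [1, {dataset.n}]"
            )
        selection = CutSelection(
            n_star=config.force_k,
            c_max=curve.max_value,
            tolerance=config.tolerance,
            forced=True,
        )
    else:
        selection = stage("selection", select_nstar, curve, config.tolerance)

    raw = cut_dendrogram(tree, selection.n_star)
    groups, _ = stage("risk_ordering", _risk_ordered_groups, dataset, raw, horizon)
    group_of = np.asarray(groups.group_of)
    km_per_group = []
    for g in range(groups.k):
        members = np.flatnonzero(group_of == g)
        times = np.concatenate([dataset.times(i) for i in members])
        events = np.concatenate([dataset.events(i) for i in members])
        km_per_group.append(km_estimate((times, events)))

    return PrognosticSystem(
        labels=dataset.labels,
        dendrogram=tree,
        curve=curve,
        selection=selection,
        groups=groups,
        c_index=curve.value_at(selection.n_star),
        km_per_group=tuple(km_per_group),
        config=config,
        horizon=horizon,
        dropped=dataset.dropped,
    )


@dataclass(frozen=True)
class ExternalGroupingResult:
    """Evaluation of an externally supplied staging over the same patients."""

    c_index: float
    group_names: tuple[str, ...]  # ordered by increasing risk
    km_per_group: tuple[KMCurve, ...]


def evaluate_external_grouping(
    dataset: CombinationDataset,
    mapping: Mapping[str, str],
    horizon: float,
) -> ExternalGroupingResult:
    """C-index and per-group KM curves for a combination -> group mapping.

    Enables head-to-head comparison of a learned system against an external
    staging (the per-group curves expose overlap/crossing).

    Raises
    ------
    EaccdError
        If any retained combination is missing from the mapping (all
        missing labels are listed).
    """
    missing = [label for label in dataset.labels if label not in mapping]
    if missing:
        raise EaccdError(f"mapping misses combinations: {missing}")
    names = sorted({mapping[label] for label in dataset.labels})
    name_idx = {name: i for i, name in enumerate(names)}
    raw = GroupAssignment(
        k=len(names),
        group_of=tuple(name_idx[mapping[label]] for label in dataset.labels),
    )
    c = c_index_of_grouping(dataset, raw, horizon)
    ordered, _ = _risk_ordered_groups(dataset, raw, horizon)

    # Recover which external name landed at each risk rank.
    rank_of_name: dict[int, str] = {}
    for label, g in zip(dataset.labels, ordered.group_of):
        rank_of_name.setdefault(g, mapping[label])
    ordered_names = tuple(rank_of_name[g] for g in range(ordered.k))

    group_of = np.asarray(ordered.group_of)
    kms = []
    for g in range(ordered.k):
        members = np.flatnonzero(group_of == g)
        times = np.concatenate([dataset.times(i) for i in members])
        events = np.concatenate([dataset.events(i) for i in members])
        kms.append(km_estimate((times, events)))
    return ExternalGroupingResult(
        c_index=c, group_names=ordered_names, km_per_group=tuple(kms)
    )
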