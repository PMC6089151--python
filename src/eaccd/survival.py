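"""Survival-analysis primitives used throughout the pipeline.

Three estimators are provided:

* :func:`km_estimate` -- the Kaplan-Meier product-limit estimator of the
  survival function of a censored sample;
* :func:`hazard_ratio` -- the maximum-partial-likelihood hazard ratio of a
  two-sample Cox proportional-hazards model with a single binary covariate
  (Breslow handling of tied event times);
* :func:`harrell_c` -- Harrell's concordance index of a risk score against
  censored event times.

These are deliberately small, array-based implementations: the hazard-ratio
fit runs once per unordered pair of factor-level combinations (an O(n^2)
loop over combinations), and the concordance index is evaluated once per
candidate dendrogram cut, so both need predictable numerics and low
per-call overhead.

Conventions
-----------
* ``event == 1`` means the disease-specific death was observed; deaths from
  other causes must be pre-coded as censored (``event == 0``) by the caller.
* A pair ``(i, j)`` is comparable for the concordance index iff
  ``t_i < t_j`` and ``event_i == 1``; pairs with tied observed times are not
  comparable.  Risk-score ties among comparable pairs count 1/2.
* Tied event times in the Cox partial likelihood use the Breslow
  approximation; with no ties this coincides with Efron's method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EaccdError, NoComparablePairsError, NoEventsError

logger = logging.getLogger(__name__)

#: Cap on |log HR| used when the partial likelihood is monotone (e.g. all
#: events in one group occur while the other is fully at risk).  The fit is
#: then flagged ``converged=False`` but still returns a finite estimate.
LOG_HR_CAP = 20.0


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time, event indicator, and factor levels.

    Parameters
    ----------
    time:
        Positive follow-up duration in consistent units (e.g. months).
    event:
        1 if the disease-specific death was observed, 0 if censored.
    levels:
        One categorical level per configured prognostic factor, in factor
        order.  May be empty when records are used outside the
        combination machinery.
    """

    time: float
    event: int
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.time > 0:
            raise EaccdError(f"follow-up time must be positive, got {self.time!r}")
        if self.event not in (0, 1):
            raise EaccdError(f"event indicator must be 0 or 1, got {self.event!r}")



def to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(times, events)`` float/int arrays from records or arrays.

    Accepts either an iterable of :class:`SurvivalRecord` or a ready-made
    ``(times, events)`` pair (the latter avoids object overhead in hot
    loops).
    """
    if isinstance(records, tuple) and len(records) == 2:
        times = np.asarray(records[0], dtype=float)
        events = np.asarray(records[1], dtype=np.int64)
        return times, events
    recs = list(records)
    times = np.fromiter((r.time for r in recs), dtype=float, count=len(recs))
    events = np.fromiter((r.event for r in recs), dtype=np.int64, count=len(recs))
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate of a survival function.

    ``survival_probs[j]`` is the estimated S(t) for
    ``event_times[j] <= t < event_times[j + 1]``; the curve is 1 before the
    first event time.  ``at_risk[j]`` is the size of the risk set at
    ``event_times[j]``.  Censoring times shrink risk sets but add no step.
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = int(np.searchsorted(self.event_times, t, side="right")) - 1
        if idx < 0:
            return 1.0
        return float(self.survival_probs[idx])

    def restricted_mean(self, horizon: float) -> float:
        """Area under the curve on [0, horizon] (restricted mean survival)."""
        if not horizon > 0:
            raise EaccdError(f"horizon must be positive, got {horizon!r}")
        knots = np.concatenate(
            ([0.0], np.minimum(self.event_times, horizon), [horizon])
        )
        probs = np.concatenate(([1.0], self.survival_probs))
        widths = np.diff(knots)
        return float(np.sum(probs * widths))


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier estimate over the distinct observed event times.

    Raises
    ------
    EaccdError
        If the input is empty or contains non-positive times.  An
        all-censored input is valid and yields a curve identically 1 with
        an empty event-time grid.
    """
    times, events = to_arrays(records)
    n = times.size
    if n == 0:
        raise EaccdError("cannot estimate a survival curve from zero records")
    if np.any(times <= 0):
        raise EaccdError("all follow-up times must be positive")

    death_times, deaths = np.unique(times[events == 1], return_counts=True)
    sorted_times = np.sort(times)
    at_risk = n - np.searchsorted(sorted_times, death_times, side="left")
    surv = np.cumprod(1.0 - deaths / at_risk)
    return KMCurve(
        event_times=death_times,
        survival_probs=surv,
        at_risk=at_risk.astype(np.int64),
        n_total=int(n),
    )


# ---------------------------------------------------------------------------
# Two-sample Cox hazard ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HazardRatioEstimate:
    """Hazard of group B relative to group A under proportional hazards."""

    hr: float
    log_hr: float
    converged: bool


def hazard_ratio(group_a, group_b) -> HazardRatioEstimate:
    """Maximum-partial-likelihood hazard ratio of ``group_b`` vs ``group_a``.

    Fits the Cox model ``h(t | z) = h0(t) exp(beta * z)`` with ``z = 1`` for
    members of ``group_b``, by Newton-Raphson on the Breslow partial
    likelihood.  Reciprocity holds to numerical tolerance:
    ``hazard_ratio(B, A).hr == 1 / hazard_ratio(A, B).hr``.

    If the likelihood is monotone in beta (complete separation of event
    histories), |log HR| is capped at :data:`LOG_HR_CAP` and the estimate is
    flagged ``converged=False``.

    Raises
    ------
    EaccdError
        If either group is empty.
    NoEventsError
        If the pooled sample contains no events (ratio unidentifiable).
    """
    ta, ea = to_arrays(group_a)
    tb, eb = to_arrays(group_b)
    if ta.size == 0 or tb.size == 0:
        raise EaccdError("both groups must contain at least one record")
    pooled_events = int(ea.sum() + eb.sum())
    if pooled_events == 0:
        raise NoEventsError("no events in the pooled sample; hazard ratio unidentifiable")

    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    death_times, d = np.unique(t_all[e_all == 1], return_counts=True)
    sa, sb = np.sort(ta), np.sort(tb)
    # Risk-set sizes per group at each distinct death time (t_j >= tau).
    n0 = ta.size - np.searchsorted(sa, death_times, side="left")
    n1 = tb.size - np.searchsorted(sb, death_times, side="left")
    d1_total = int(eb.sum())

    def loglik(beta: float) -> float:
        return beta * d1_total - float(np.sum(d * np.log(n0 + n1 * math.exp(beta))))

    def derivatives(beta: float) -> tuple[float, float]:
        expb = math.exp(beta)
        s0 = n0 + n1 * expb
        frac = n1 * expb / s0
        grad = d1_total - float(np.sum(d * frac))
        hess = -float(np.sum(d * frac * (n0 / s0)))
        return grad, hess

    beta = 0.0
    ll = loglik(beta)
    converged = False
    gtol = 1e-9 * max(1.0, pooled_events)
    for _ in range(100):
        grad, hess = derivatives(beta)
        if abs(grad) <= gtol:
            converged = True
            break
        if hess >= -1e-300:
            # Flat likelihood (e.g. one group never at risk at event times).
            converged = abs(grad) <= 1e-6 * max(1.0, pooled_events)
            break
        new_beta = beta - grad / hess
        new_beta = min(max(new_beta, -LOG_HR_CAP), LOG_HR_CAP)
        new_ll = loglik(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            new_beta = 0.5 * (beta + new_beta)
            new_ll = loglik(new_beta)
            halvings += 1
        if abs(new_ll - ll) <= 1e-12 * (abs(ll) + 1.0) and new_beta == beta:
            # Pinned at the cap with an outward gradient: monotone likelihood.
            break
        beta, ll = new_beta, new_ll

    at_cap = abs(beta) >= LOG_HR_CAP - 1e-9
    if at_cap:
        logger.warning(
            "hazard_ratio: monotone partial likelihood; |log HR| capped at %.0f",
            LOG_HR_CAP,
        )
        converged = False
    return HazardRatioEstimate(hr=math.exp(beta), log_hr=beta, converged=converged)


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------


class _Fenwick:
    """Binary indexed tree over risk-score ranks (counts only)."""

    __slots__ = ("n", "tree")

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)

    def add(self, i: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        """Count of inserted ranks <= i (0-based); -1 gives 0."""
        i += 1
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def harrell_c(times, events, risk_scores) -> float:
    """Harrell's concordance index of ``risk_scores`` against survival data.

    C = (concordant + 0.5 * risk-tied) / comparable, where pair (i, j) is
    comparable iff ``t_i < t_j`` and ``event_i == 1``, and concordant iff
    ``risk_i > risk_j`` (higher risk predicts the shorter time).

    Runs in O(n log n) via a Fenwick tree over risk ranks; exact agreement
    with all-pairs enumeration.

    Raises
    ------
    NoComparablePairsError
        If no comparable pair exists (e.g. everything censored).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=np.int64)
    r = np.asarray(risk_scores, dtype=float)
    if not (t.size == e.size == r.size):
        raise EaccdError("times, events and risk_scores must have equal length")
    n = t.size

    _, ranks = np.unique(r, return_inverse=True)
    n_ranks = int(ranks.max()) + 1 if n else 0
    idx = np.argsort(t, kind="stable")[::-1]  # descending time
    fen = _Fenwick(n_ranks)
    concordant = 0.0
    comparable = 0
    inserted = 0

    pos = 0
    while pos < n:
        j = pos
        tv = t[idx[pos]]
        while j < n and t[idx[j]] == tv:
            j += 1
        batch = idx[pos:j]
        if inserted:
            # Everything inserted so far has strictly larger time.
            for i in batch:
                if e[i] == 1:
                    below = fen.prefix(int(ranks[i]) - 1)
                    tied = fen.prefix(int(ranks[i])) - below
                    concordant += below + 0.5 * tied
                    comparable += inserted
        for i in batch:
            fen.add(int(ranks[i]))
        inserted = j
        pos = j

    if comparable == 0:
        raise NoComparablePairsError("no comparable pairs; concordance index undefined")
    return concordant / comparable
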