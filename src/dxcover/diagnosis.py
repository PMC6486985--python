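"""Candidate filtering, scoring, and the weighted set-cover diagnosis engine.

Given a patient case (a set of observed findings plus optional demographics),
candidate explanations are first filtered by hard constraints — negating
findings, binary geographic presence, age group, sex — and then scored.

Two query modes are provided:

* **single-explanation ranking** (:func:`rank_differential`): each eligible
  explanation d is scored additively, ``score(d) = Σ_s w(s, d)`` over observed
  findings with positive weight, and the top k form the differential.
* **multi-explanation set cover** (:func:`greedy_cover`): find a small set D
  of explanations maximizing the symptom cover weight

      m(D) = Σ_s max(0, max_{d ∈ D} w(s, d)),

  the classic weighted maximum-coverage objective.  m is monotone and
  submodular, so the greedy algorithm that repeatedly adds the explanation
  with the largest marginal gain m(D ∪ {d}) − m(D) carries the usual
  (1 − 1/e) approximation guarantee.  :func:`brute_force_cover` is an
  exhaustive oracle for small instances.

A naive-Bayes scorer (:func:`bayes_score`) is included as an alternative
ranking mode: weights are read as conditional frequencies P(s | d) and
combined with a prior over eligible candidates.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import IneligibleExplanationError, QueryError
from .kb import KnowledgeBase, Sex, age_group_of

__all__ = [
    "PatientCase",
    "ExplanationSet",
    "RankedCandidate",
    "Differential",
    "SCORE_TOL",
    "bayes_posteriors",
    "bayes_score",
    "brute_force_cover",
    "cover_weight",
    "eligible_candidates",
    "greedy_cover",
    "rank_differential",
    "single_score",
]

logger = logging.getLogger(__name__)

#: Two scores within this tolerance are treated as tied.
SCORE_TOL = 1e-9

#: Greedy stops when the best marginal gain falls to or below this value.
DEFAULT_EPSILON = 1e-12

#: Likelihood floor for observed findings with no positive association to a
#: candidate (keeps one unrecorded finding from hard-zeroing a candidate in a
#: sparse knowledge base).
BAYES_FLOOR = 0.01

_BRUTE_FORCE_GUARD = 20


@dataclass(frozen=True)
class PatientCase:
    """The query: observed finding ids plus optional demographic context.

    Unspecified fields (``age_months``/``sex`` of ``None``, empty
    ``regions``) impose no eligibility filter.
    """

    case_id: str
    observed: frozenset[str]
    age_months: int | None = None
    sex: str | None = None  # "MALE" | "FEMALE" | None
    regions: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RankedCandidate:
    explanation_id: str
    score: float
    n_matched: int
    tie_group: int


@dataclass(frozen=True)
class Differential:
    """Ranked single-explanation differential, truncated to ``truncated_at``.

    ``tie_cut_flag`` is True when the last shown candidate ties (within
    :data:`SCORE_TOL`) with the first hidden one — the correct answer may sit
    just past the cut despite an equal score.
    """

    case_id: str
    candidates: tuple[RankedCandidate, ...]
    truncated_at: int
    tie_cut_flag: bool

    def rank_of(self, explanation_id: str) -> int | None:
        """1-based rank of an explanation in the shown list, else None."""
        for i, c in enumerate(self.candidates, start=1):
            if c.explanation_id == explanation_id:
                return i
        return None


@dataclass(frozen=True)
class ExplanationSet:
    """A multi-explanation answer: members in pick order with their marginal
    gains; ``cover_value`` is m(members) and equals the sum of gains."""

    members: tuple[str, ...]
    cover_value: float
    gain_trace: tuple[float, ...] = field(default=())


def _check_observed(kb: KnowledgeBase, case: PatientCase) -> None:
    unknown = sorted(f for f in case.observed if f not in kb.findings)
    if unknown:
        raise QueryError(
            f"case {case.case_id}: unknown observed finding id(s): "
            + ", ".join(unknown)
        )


def eligible_candidates(kb: KnowledgeBase, case: PatientCase) -> set[str]:
    """Explanation ids surviving the hard filters for this case.

    An explanation is excluded when (a) it negates (weight −1) any observed
    finding, (b) its region set and the case's are both non-empty and
    disjoint, (c) it constrains age groups and the case's age falls outside,
    or (d) its sex constraint conflicts with the case's stated sex.
    """
    _check_observed(kb, case)
    case_group = age_group_of(case.age_months) if case.age_months is not None else None
    out: set[str] = set()
    for eid, expl in kb.explanations.items():
        if expl.regions and case.regions and not (expl.regions & case.regions):
            continue
        if expl.age_groups and case_group is not None and case_group not in expl.age_groups:
            continue
        if case.sex == "MALE" and expl.sex is Sex.FEMALE_ONLY:
            continue
        if case.sex == "FEMALE" and expl.sex is Sex.MALE_ONLY:
            continue
        if any(
            a.weight == -1 and a.finding_id in case.observed
            for a in kb.by_explanation.get(eid, ())
        ):
            continue
        out.add(eid)
    return out


def single_score(kb: KnowledgeBase, explanation_id: str, case: PatientCase) -> float:
    """Additive score: sum of positive weights over observed findings."""
    if explanation_id not in eligible_candidates(kb, case):
        raise IneligibleExplanationError(
            f"{explanation_id} is not eligible for case {case.case_id}"
        )
    return _raw_single_score(kb, explanation_id, case.observed)


def _raw_single_score(
    kb: KnowledgeBase, explanation_id: str, observed: frozenset[str]
) -> float:
    return sum(
        a.weight
        for a in kb.by_explanation.get(explanation_id, ())
        if a.weight > 0 and a.finding_id in observed
    )


def cover_weight(
    kb: KnowledgeBase, members: Iterable[str], case: PatientCase
) -> float:
    """Symptom cover weight m(D) = Σ_s max(0, max_{d∈D} w(s, d))."""
    _check_observed(kb, case)
    members = list(members)
    total = 0.0
    for s in case.observed:
        best = 0.0
        for d in members:
            w = kb.weight(d, s)
            if w is not None and w > best:
                best = w
        total += best
    return total


def greedy_cover(
    kb: KnowledgeBase,
    case: PatientCase,
    max_size: int = 3,
    epsilon: float = DEFAULT_EPSILON,
) -> ExplanationSet:
    """Greedy weighted maximum coverage.

    At each step adds the eligible explanation with the largest marginal gain
    m(D ∪ {d}) − m(D), ties broken by explanation id ascending; stops when
    the best gain drops to ``epsilon`` or the set reaches ``max_size``.
    Returns the empty set (cover_value 0) when nothing is eligible.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    pool = sorted(eligible_candidates(kb, case))
    # per-symptom best weight achieved so far; gains computed incrementally
    best_so_far: dict[str, float] = {s: 0.0 for s in case.observed}
    members: list[str] = []
    gains: list[float] = []
    for _ in range(max_size):
        best_gain = -math.inf
        best_id: str | None = None
        for d in pool:
            if d in members:
                continue
            gain = 0.0
            for a in kb.by_explanation.get(d, ()):
                if a.weight > 0 and a.finding_id in best_so_far:
                    gain += max(0.0, a.weight - best_so_far[a.finding_id])
            if gain > best_gain + SCORE_TOL or (
                abs(gain - best_gain) <= SCORE_TOL
                and best_id is not None
                and d < best_id
            ):
                best_gain, best_id = gain, d
        if best_id is None or best_gain <= epsilon:
            break
        members.append(best_id)
        gains.append(best_gain)
        for a in kb.by_explanation.get(best_id, ()):
            if a.weight > 0 and a.finding_id in best_so_far:
                best_so_far[a.finding_id] = max(best_so_far[a.finding_id], a.weight)
    return ExplanationSet(
        members=tuple(members),
        cover_value=sum(gains),
        gain_trace=tuple(gains),
    )


def _ordered_by_internal_greedy(
    kb: KnowledgeBase, members: Sequence[str], case: PatientCase
) -> tuple[tuple[str, ...], tuple[float, ...]]:
    """Order a fixed member set by within-set greedy pick, so the gain trace
    is non-increasing (submodularity) and sums to m(members)."""
    remaining = sorted(members)
    best_so_far: dict[str, float] = {s: 0.0 for s in case.observed}
    order: list[str] = []
    gains: list[float] = []
    while remaining:
        best_gain, best_id = -math.inf, remaining[0]
        for d in remaining:
            gain = 0.0
            for a in kb.by_explanation.get(d, ()):
                if a.weight > 0 and a.finding_id in best_so_far:
                    gain += max(0.0, a.weight - best_so_far[a.finding_id])
            if gain > best_gain + SCORE_TOL:
                best_gain, best_id = gain, d
        order.append(best_id)
        gains.append(best_gain)
        remaining.remove(best_id)
        for a in kb.by_explanation.get(best_id, ()):
            if a.weight > 0 and a.finding_id in best_so_far:
                best_so_far[a.finding_id] = max(best_so_far[a.finding_id], a.weight)
    return tuple(order), tuple(gains)


def brute_force_cover(
    kb: KnowledgeBase, case: PatientCase, max_size: int = 3
) -> ExplanationSet:
    """Exhaustive oracle: maximize m over all subsets of size ≤ max_size.

    Among maximizers prefers the smaller set, then the lexicographically
    smallest member tuple.  Refuses instances with more than 20 eligible
    candidates (exponential blow-up); use :func:`greedy_cover` there.
    """
    pool = sorted(eligible_candidates(kb, case))
    if len(pool) > _BRUTE_FORCE_GUARD:
        raise QueryError(
            f"brute_force_cover refuses {len(pool)} candidates (> "
            f"{_BRUTE_FORCE_GUARD}); use greedy_cover"
        )
    best_value = 0.0
    best_set: tuple[str, ...] = ()
    for size in range(0, max_size + 1):
        for combo in itertools.combinations(pool, size):
            value = cover_weight(kb, combo, case)
            if value > best_value + SCORE_TOL:
                best_value, best_set = value, combo
            # equal value: smaller size already preferred by loop order;
            # equal size: lexicographic order of combinations keeps the first
    order, gains = _ordered_by_internal_greedy(kb, best_set, case)
    return ExplanationSet(members=order, cover_value=best_value, gain_trace=gains)


def rank_differential(kb: KnowledgeBase, case: PatientCase, k: int = 20) -> Differential:
    """Single-explanation differential: eligible explanations scored
    additively, sorted (score desc, id asc), zero scores omitted, truncated
    to ``k`` with tie-group labels and the tie cut-off flag."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [
        (eid, _raw_single_score(kb, eid, case.observed))
        for eid in eligible_candidates(kb, case)
    ]
    scored = [(eid, s) for eid, s in scored if s > 0]
    scored.sort(key=lambda t: (-t[1], t[0]))
    # tie groups over the untruncated list
    groups: list[int] = []
    group = 0
    for i, (_, s) in enumerate(scored):
        if i and abs(s - scored[i - 1][1]) > SCORE_TOL:
            group += 1
        groups.append(group)
    tie_cut = len(scored) > k and abs(scored[k - 1][1] - scored[k][1]) <= SCORE_TOL
    shown = []
    for (eid, s), g in list(zip(scored, groups))[:k]:
        n_matched = sum(
            1
            for a in kb.by_explanation.get(eid, ())
            if a.weight > 0 and a.finding_id in case.observed
        )
        shown.append(
            RankedCandidate(explanation_id=eid, score=s, n_matched=n_matched, tie_group=g)
        )
    return Differential(
        case_id=case.case_id,
        candidates=tuple(shown),
        truncated_at=k,
        tie_cut_flag=tie_cut,
    )


def bayes_posteriors(
    kb: KnowledgeBase,
    case: PatientCase,
    priors: Mapping[str, float] | None = None,
    floor: float = BAYES_FLOOR,
) -> dict[str, float]:
    """Naive-Bayes posterior over eligible candidates.

    Each candidate's likelihood is the product over observed findings of
    ``max(w(s, d), floor)`` (weights read as P(s | d)); multiplied by the
    prior (uniform over eligible candidates by default) and normalized so the
    posteriors sum to 1 — the normalization constant plays the role of the
    evidence P(observations).
    """
    eligible = sorted(eligible_candidates(kb, case))
    if not eligible:
        return {}
    if priors is None:
        priors = {eid: 1.0 / len(eligible) for eid in eligible}
    scores: dict[str, float] = {}
    for eid in eligible:
        weights = {
            a.finding_id: a.weight
            for a in kb.by_explanation.get(eid, ())
            if a.weight > 0
        }
        like = priors.get(eid, 0.0)
        for s in case.observed:
            like *= max(weights.get(s, 0.0), floor)
        scores[eid] = like
    total = sum(scores.values())
    if total <= 0.0:
        logger.warning(
            "case %s: all candidate likelihoods zero; returning uniform posterior",
            case.case_id,
        )
        return {eid: 1.0 / len(eligible) for eid in eligible}
    return {eid: v / total for eid, v in scores.items()}


def bayes_score(
    kb: KnowledgeBase,
    explanation_id: str,
    case: PatientCase,
    priors: Mapping[str, float] | None = None,
    floor: float = BAYES_FLOOR,
) -> float:
    """Posterior probability of one eligible explanation (see
    :func:`bayes_posteriors`)."""
    post = bayes_posteriors(kb, case, priors=priors, floor=floor)
    if explanation_id not in post:
        raise IneligibleExplanationError(
            f"{explanation_id} is not eligible for case {case.case_id}"
        )
    return post[explanation_id]
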