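"""Synthetic knowledge bases and patient cases with realistic shape.

The generator emulates the statistical shape of a curated diagnostic
knowledge base of roughly 2000 explanations and 8000 findings: a long-tailed
distribution of positive findings per explanation (about 14% of explanations
described by a single finding, 42% by five or fewer, 28% by ten or more, with
a tail reaching ~67), weights drawn from a small set of frequency anchors,
sparse −1 negations, binary region presence on a continent vocabulary, and
occasional age/sex constraints.

The degree law is a single-inflated negative binomial shifted to a minimum of
one finding and truncated at the maximum; its three parameters are fitted at
generation time by least squares against the three shape anchors, so the
anchors — not the law's parameters — are the configuration surface.

Patient cases are sampled from a ground-truth explanation: each positively
weighted finding is observed with probability ``observe_prob(weight)``
(default: the weight itself, i.e. the literal frequency reading of the
weights), negated findings are never observed, and ``n_spurious`` distractor
findings are added uniformly from unrelated findings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .diagnosis import PatientCase, rank_differential
from .errors import ConfigError, GenerationError
from .evaluation import MISS, EvaluationRecord, SummaryRow, summarize
from .kb import (
    AgeGroup,
    Association,
    CodeSystem,
    Explanation,
    ExplanationKind,
    Finding,
    KnowledgeBase,
    Sex,
    Vocabulary,
)

__all__ = [
    "CaseModel",
    "LabeledCase",
    "SyntheticConfig",
    "generate_cases",
    "generate_kb",
    "load_labeled_cases",
    "recovery_experiment",
    "save_labeled_cases",
    "truth_rank",
]

_REGIONS = ("Africa", "Asia", "Europe", "NorthAmerica", "SouthAmerica", "Oceania")

#: Age ranges (months, inclusive-exclusive) used to sample a case age inside
#: a required age group.
_GROUP_MONTH_RANGES = {
    AgeGroup.INFANT: (0, 6),
    AgeGroup.CHILD: (6, 156),
    AgeGroup.ADULT: (156, 732),
    AgeGroup.ELDERLY: (732, 1200),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the knowledge-base generator.

    Degree anchors target the shape of the real KB's findings-per-explanation
    distribution; ``weight_probs`` is the mixture over the textual-frequency
    anchor weights (the real distribution is unpublished, so this default is
    configuration, not a measured quantity).
    """

    n_explanations: int = 2000
    n_findings: int = 8000
    pct_single_target: float = 0.14
    pct_le5_target: float = 0.42
    pct_ge10_target: float = 0.28
    max_degree: int = 67
    weight_anchors: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 0.75, 1.0)
    weight_probs: tuple[float, ...] = (0.10, 0.15, 0.25, 0.25, 0.15, 0.10)
    negation_rate: float = 0.05
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.08 for r in _REGIONS}
    )
    medication_fraction: float = 0.18
    age_constraint_rate: float = 0.10
    sex_constraint_rate: float = 0.05
    unique_signatures: bool = False
    fixed_degree: int | None = None
    seed: int = 0

    def check(self) -> None:
        if self.n_explanations < 1 or self.n_findings < 1:
            raise ConfigError("counts must be >= 1")
        probs = list(self.weight_probs) + [
            self.negation_rate,
            self.medication_fraction,
            self.age_constraint_rate,
            self.sex_constraint_rate,
            *self.region_probs.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if len(self.weight_probs) != len(self.weight_anchors):
            raise ConfigError("weight_probs must match weight_anchors in length")
        if abs(sum(self.weight_probs) - 1.0) > 1e-9:
            raise ConfigError("weight_probs must sum to 1")
        if self.fixed_degree is not None and self.fixed_degree > self.n_findings:
            raise ConfigError(
                f"fixed_degree {self.fixed_degree} exceeds n_findings "
                f"{self.n_findings}"
            )
        if self.max_degree > self.n_findings:
            raise ConfigError(
                f"max_degree {self.max_degree} exceeds n_findings {self.n_findings}"
            )


@dataclass(frozen=True)
class CaseModel:
    """Observation model for case sampling.

    ``observe_prob`` maps an association weight to the probability the
    finding is observed; the identity default treats weights as literal
    conditional frequencies.
    """

    observe_prob: Callable[[float], float] = lambda w: w
    n_spurious: int = 0
    seed: int = 0


@dataclass(frozen=True)
class LabeledCase:
    """A generated case together with its ground-truth explanation."""

    case: PatientCase
    true_explanation_id: str


# ---------------------------------------------------------------------------
# Degree law
# ---------------------------------------------------------------------------

def _truncated_nb_pmf(r: float, p: float, max_degree: int) -> np.ndarray:
    """pmf over degrees 1..max_degree for 1 + NB(r, p) truncated above."""
    k = np.arange(0, max_degree)  # NB support 0..max-1 -> degree 1..max
    pmf = stats.nbinom.pmf(k, r, p)
    total = pmf.sum()
    if total <= 0:
        return np.full(max_degree, 1.0 / max_degree)
    return pmf / total


def _mixture_pmf(params: np.ndarray, max_degree: int) -> np.ndarray:
    """Single-inflated truncated negative binomial over degrees 1..max.

    An extra point mass at degree 1 gives the law a third parameter, enough
    to match all three shape anchors (single, <=5, >=10) simultaneously.
    """
    pi = float(expit(params[0]))
    r = math.exp(min(params[1], 20.0))
    p = float(expit(params[2]))
    pmf = _truncated_nb_pmf(r, p, max_degree).copy()
    pmf *= 1.0 - pi
    pmf[0] += pi
    return pmf


def _anchor_error(params: np.ndarray, cfg: SyntheticConfig) -> float:
    pmf = _mixture_pmf(params, cfg.max_degree)
    single = pmf[0]
    le5 = pmf[:5].sum()
    ge10 = pmf[9:].sum()
    return (
        (single - cfg.pct_single_target) ** 2
        + (le5 - cfg.pct_le5_target) ** 2
        + (ge10 - cfg.pct_ge10_target) ** 2
    )


def _fit_degree_pmf(cfg: SyntheticConfig) -> np.ndarray:
    """Least-squares fit of the degree law to the three shape anchors."""
    best = None
    for x0 in ([-2.0, 0.0, 0.0], [-2.0, math.log(2.0), -1.0], [-1.0, math.log(0.7), -2.0]):
        res = optimize.minimize(
            _anchor_error, np.array(x0), args=(cfg,), method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return _mixture_pmf(best.x, cfg.max_degree)


# ---------------------------------------------------------------------------
# Knowledge-base generation
# ---------------------------------------------------------------------------

def generate_kb(config: SyntheticConfig) -> KnowledgeBase:
    """Generate a valid knowledge base with the configured shape.

    Deterministic for identical config and seed.  With
    ``unique_signatures=True`` every explanation receives a disjoint block of
    findings (raises :class:`ConfigError` if the finding pool is too small).
    """
    config.check()
    rng = np.random.default_rng(config.seed)
    n_e, n_f = config.n_explanations, config.n_findings

    if config.fixed_degree is not None:
        degrees = np.full(n_e, config.fixed_degree, dtype=int)
    else:
        pmf = _fit_degree_pmf(config)
        degrees = rng.choice(np.arange(1, config.max_degree + 1), size=n_e, p=pmf)
    if config.unique_signatures and int(degrees.sum()) > n_f:
        raise ConfigError(
            f"unique signatures need {int(degrees.sum())} findings but only "
            f"{n_f} exist; raise n_findings"
        )

    width_f = max(5, len(str(n_f)))
    width_e = max(5, len(str(n_e)))
    findings = [
        Finding(
            finding_id=f"F{i:0{width_f}d}",
            label=f"finding {i:0{width_f}d}",
            vocabulary=Vocabulary.LOCAL,
        )
        for i in range(1, n_f + 1)
    ]
    finding_ids = np.array([f.finding_id for f in findings])

    explanations: list[Explanation] = []
    associations: list[Association] = []
    pool = rng.permutation(n_f)  # for disjoint block assignment
    cursor = 0
    anchors = np.asarray(config.weight_anchors)
    wprobs = np.asarray(config.weight_probs)
    region_items = sorted(config.region_probs.items())
    for j in range(1, n_e + 1):
        eid = f"E{j:0{width_e}d}"
        is_med = rng.random() < config.medication_fraction
        kind = ExplanationKind.MEDICATION if is_med else ExplanationKind.DISEASE
        regions = frozenset(
            tag for tag, pr in region_items if rng.random() < pr
        )
        age_groups: frozenset[AgeGroup] = frozenset()
        if rng.random() < config.age_constraint_rate:
            k = int(rng.integers(1, 4))
            age_groups = frozenset(
                AgeGroup(g)
                for g in rng.choice(
                    [g.value for g in AgeGroup], size=k, replace=False
                )
            )
        sex = Sex.ANY
        if rng.random() < config.sex_constraint_rate:
            sex = Sex.MALE_ONLY if rng.random() < 0.5 else Sex.FEMALE_ONLY
        explanations.append(
            Explanation(
                explanation_id=eid,
                label=f"{'medication' if is_med else 'disease'} {j:0{width_e}d}",
                kind=kind,
                code_system=CodeSystem.LOCAL,
                regions=regions,
                age_groups=age_groups,
                sex=sex,
            )
        )
        deg = int(degrees[j - 1])
        if config.unique_signatures:
            chosen = pool[cursor: cursor + deg]
            cursor += deg
        else:
            chosen = rng.choice(n_f, size=deg, replace=False)
        weights = rng.choice(anchors, size=deg, p=wprobs)
        linked = set()
        for fi, w in zip(chosen, weights):
            associations.append(
                Association(
                    explanation_id=eid,
                    finding_id=str(finding_ids[fi]),
                    weight=float(w),
                )
            )
            linked.add(int(fi))
        if rng.random() < config.negation_rate:
            # negate one finding not already positively linked
            for _ in range(20):
                fi = int(rng.integers(0, n_f))
                if fi not in linked:
                    associations.append(
                        Association(
                            explanation_id=eid,
                            finding_id=str(finding_ids[fi]),
                            weight=-1.0,
                        )
                    )
                    break
    return KnowledgeBase.build(findings, explanations, associations)


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

_MAX_RESAMPLE = 200


def _sample_demographics(
    rng: np.random.Generator, expl: Explanation
) -> tuple[int, str, frozenset[str]]:
    """Age, sex, regions consistent with the truth's constraints."""
    groups = sorted(expl.age_groups, key=lambda g: g.value) or list(AgeGroup)
    group = groups[int(rng.integers(0, len(groups)))]
    lo, hi = _GROUP_MONTH_RANGES[group]
    age = int(rng.integers(lo, hi))
    if expl.sex is Sex.MALE_ONLY:
        sex = "MALE"
    elif expl.sex is Sex.FEMALE_ONLY:
        sex = "FEMALE"
    else:
        sex = "MALE" if rng.random() < 0.5 else "FEMALE"
    if expl.regions:
        regions = frozenset({sorted(expl.regions)[int(rng.integers(0, len(expl.regions)))]})
    else:
        regions = frozenset()
    return age, sex, regions


def generate_cases(
    kb: KnowledgeBase, n_cases: int, model: CaseModel
) -> list[LabeledCase]:
    """Sample labeled cases from the knowledge base.

    Each case draws a ground-truth explanation uniformly among those with at
    least one positive association, observes each of its positive findings
    with ``observe_prob(weight)``, never observes findings the truth negates,
    and adds ``n_spurious`` distractors from unrelated findings.  Cases with
    zero observed findings are resampled (after 200 empty draws the truth's
    strongest finding is observed directly, guaranteeing termination).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    eligible_truths = sorted(
        eid for eid in kb.explanations if kb.positive_findings(eid)
    )
    if not eligible_truths:
        raise GenerationError("knowledge base has no positive associations")
    rng = np.random.default_rng(model.seed)
    all_findings = np.array(sorted(kb.findings))
    out: list[LabeledCase] = []
    for i in range(1, n_cases + 1):
        truth = eligible_truths[int(rng.integers(0, len(eligible_truths)))]
        expl = kb.explanations[truth]
        positives = sorted(kb.positive_findings(truth).items())
        negated = kb.negated_findings(truth)
        observed: set[str] = set()
        for _ in range(_MAX_RESAMPLE):
            observed = {
                fid for fid, w in positives if rng.random() < model.observe_prob(w)
            }
            if observed:
                break
        else:
            observed = {max(positives, key=lambda kv: (kv[1], kv[0]))[0]}
        if model.n_spurious:
            forbidden = {fid for fid, _ in positives} | negated
            candidates = np.array([f for f in all_findings if f not in forbidden])
            k = min(model.n_spurious, candidates.size)
            observed |= set(
                candidates[rng.choice(candidates.size, size=k, replace=False)]
            )
        age, sex, regions = _sample_demographics(rng, expl)
        out.append(
            LabeledCase(
                case=PatientCase(
                    case_id=f"C{i:05d}",
                    observed=frozenset(observed),
                    age_months=age,
                    sex=sex,
                    regions=regions,
                ),
                true_explanation_id=truth,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

def truth_rank(kb: KnowledgeBase, lcase: LabeledCase, k: int = 20) -> int | None:
    """Rank of the ground-truth explanation in the differential, or MISS."""
    diff = rank_differential(kb, lcase.case, k=k)
    return diff.rank_of(lcase.true_explanation_id)


def recovery_experiment(
    kb: KnowledgeBase,
    conditions: Mapping[str, Sequence[LabeledCase]],
    k: int = 20,
    tool: str = "set-cover",
) -> list[SummaryRow]:
    """Rank the ground truth for every case of every condition and summarize.

    ``conditions`` maps a condition label (e.g. a noise level) to its cases;
    the label becomes the dataset of the emitted evaluation records, so the
    result is one summary row per condition.
    """
    records: list[EvaluationRecord] = []
    for label, cases in conditions.items():
        for lc in cases:
            missing = [f for f in lc.case.observed if f not in kb.findings]
            if missing or lc.true_explanation_id not in kb.explanations:
                raise GenerationError(
                    f"case {lc.case.case_id} does not belong to this knowledge base"
                )
            rank = truth_rank(kb, lc, k=k)
            records.append(
                EvaluationRecord(
                    case_id=lc.case.case_id,
                    tool=tool,
                    dataset=label,
                    rank=rank if rank is not None else MISS,
                )
            )
    rows = summarize(records, group_by=("dataset",))
    order = {label: i for i, label in enumerate(conditions)}
    rows.sort(key=lambda r: order.get(r.group[0], len(order)))
    return rows


# ---------------------------------------------------------------------------
# Case I/O (cases table + ground-truth sidecar)
# ---------------------------------------------------------------------------

_CASE_COLS = ["case_id", "observed", "age_months", "sex", "regions"]


def save_labeled_cases(
    labeled: Sequence[LabeledCase],
    cases_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Write cases (observed ids semicolon-joined) and the truth sidecar."""
    rows = [
        {
            "case_id": lc.case.case_id,
            "observed": ";".join(sorted(lc.case.observed)),
            "age_months": "" if lc.case.age_months is None else str(lc.case.age_months),
            "sex": lc.case.sex or "",
            "regions": ";".join(sorted(lc.case.regions)),
        }
        for lc in labeled
    ]
    pd.DataFrame(rows, columns=_CASE_COLS).to_csv(
        cases_path, index=False, lineterminator="\n"
    )
    pd.DataFrame(
        [
            {"case_id": lc.case.case_id, "true_explanation_id": lc.true_explanation_id}
            for lc in labeled
        ],
        columns=["case_id", "true_explanation_id"],
    ).to_csv(truth_path, index=False, lineterminator="\n")


def load_labeled_cases(
    cases_path: str | Path, truth_path: str | Path
) -> list[LabeledCase]:
    cdf = pd.read_csv(cases_path, dtype=str, na_filter=False)
    tdf = pd.read_csv(truth_path, dtype=str, na_filter=False)
    truth = dict(zip(tdf["case_id"], tdf["true_explanation_id"]))
    out: list[LabeledCase] = []
    for r in cdf.itertuples():
        out.append(
            LabeledCase(
                case=PatientCase(
                    case_id=r.case_id,
                    observed=frozenset(t for t in r.observed.split(";") if t),
                    age_months=int(r.age_months) if r.age_months else None,
                    sex=r.sex or None,
                    regions=frozenset(t for t in r.regions.split(";") if t),
                ),
                true_explanation_id=truth[r.case_id],
            )
        )
    return out
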