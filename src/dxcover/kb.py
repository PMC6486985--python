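"""Knowledge-base data model, serialization, validation and summary statistics.

The knowledge base is a weighted bipartite relation between *explanations*
(diseases or medication side effects) and *findings* (signs, symptoms, lab and
imaging observations).  Each association carries a weight ``w(s, d)`` in
``[0, 1]`` interpreted as the conditional frequency of finding ``s`` given
explanation ``d``; the special weight ``-1`` marks a *negating* relation
(the finding is incompatible with the explanation, e.g. rash rules out
malaria).  Explanations additionally carry binary geographic priors (a set of
region tags), broad age-group constraints and a sex constraint.

Canonical on-disk form is a directory of three UTF-8 CSV tables
(``findings.csv``, ``explanations.csv``, ``associations.csv``); a single YAML
document carrying the same fields is accepted as an alternative.  Saving is
byte-stable: rows are written in sorted id order with a fixed number format,
so two saves of the same knowledge base produce identical files.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    EncodingError,
    IntegrityError,
    LoadError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "AgeGroup",
    "Association",
    "Explanation",
    "ExplanationKind",
    "CodeSystem",
    "Finding",
    "KbStats",
    "KnowledgeBase",
    "Sex",
    "Vocabulary",
    "TEXTUAL_WEIGHTS",
    "DEFAULT_REGIONS",
    "NEGATING",
    "age_group_of",
    "autocomplete",
    "encode_frequency",
    "kb_statistics",
    "load_knowledge_base",
    "save_knowledge_base",
    "validate",
]


class Vocabulary(str, enum.Enum):
    """Terminology a finding is coded in. LOCAL codes are never resolved."""

    SNOMED = "SNOMED"
    LOINC = "LOINC"
    LOCAL = "LOCAL"


class ExplanationKind(str, enum.Enum):
    DISEASE = "DISEASE"
    MEDICATION = "MEDICATION"


class CodeSystem(str, enum.Enum):
    ICD10 = "ICD10"
    RXNORM = "RXNORM"
    LOCAL = "LOCAL"


class Sex(str, enum.Enum):
    """Sex constraint on an explanation; ANY imposes no filter."""

    ANY = "ANY"
    MALE_ONLY = "MALE_ONLY"
    FEMALE_ONLY = "FEMALE_ONLY"


class AgeGroup(str, enum.Enum):
    """Broad age buckets: infant (0-6 mo), child (6 mo-12 y), adult
    (13-60 y), elderly (>60 y)."""

    INFANT = "INFANT"
    CHILD = "CHILD"
    ADULT = "ADULT"
    ELDERLY = "ELDERLY"


#: Default region vocabulary (region tags are otherwise free strings).
DEFAULT_REGIONS = frozenset(
    {"Africa", "Asia", "Europe", "NorthAmerica", "SouthAmerica", "Oceania"}
)

#: Sentinel token accepted by :func:`encode_frequency` for negating relations.
NEGATING = "negating"

#: Textual frequency terms and their weight anchors.  This table is
#: configuration, not doctrine: curation teams may substitute their own
#: mapping; the anchors below are uniform reference points.
TEXTUAL_WEIGHTS: dict[str, float] = {
    "always": 1.0,
    "all": 1.0,
    "most": 0.75,
    "usually": 0.75,
    "often": 0.5,
    "common": 0.5,
    "sometimes": 0.25,
    "occasional": 0.25,
    "occasionally": 0.25,
    "rare": 0.05,
    "rarely": 0.05,
    "never": 0.0,
    NEGATING: -1.0,
}


@dataclass(frozen=True)
class Finding:
    """A sign, symptom, demographic attribute or test result."""

    finding_id: str
    label: str
    vocabulary: Vocabulary = Vocabulary.LOCAL
    code: str = ""


@dataclass(frozen=True)
class Explanation:
    """A candidate cause: an ICD-10 coded disease or RxNorm coded medication.

    ``regions``, ``age_groups`` empty and ``sex == ANY`` mean "no constraint";
    permissive defaults keep partially curated entries usable.
    """

    explanation_id: str
    label: str
    kind: ExplanationKind = ExplanationKind.DISEASE
    code_system: CodeSystem = CodeSystem.LOCAL
    code: str = ""
    regions: frozenset[str] = frozenset()
    age_groups: frozenset[AgeGroup] = frozenset()
    sex: Sex = Sex.ANY


@dataclass(frozen=True)
class Association:
    """Weighted link: w(s, d) in [0, 1], or exactly -1 for a negation."""

    explanation_id: str
    finding_id: str
    weight: float


@dataclass
class KnowledgeBase:
    """Findings, explanations, associations, plus id-keyed indexes.

    Construct via :meth:`build` so the per-finding and per-explanation
    association indexes stay consistent with the association list.
    """

    findings: dict[str, Finding]
    explanations: dict[str, Explanation]
    associations: list[Association]
    by_finding: dict[str, list[Association]] = field(default_factory=dict)
    by_explanation: dict[str, list[Association]] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        findings: Iterable[Finding],
        explanations: Iterable[Explanation],
        associations: Iterable[Association],
    ) -> "KnowledgeBase":
        fmap: dict[str, Finding] = {}
        for f in findings:
            if f.finding_id in fmap:
                raise ValidationError(f"duplicate finding_id {f.finding_id!r}")
            fmap[f.finding_id] = f
        emap: dict[str, Explanation] = {}
        for e in explanations:
            if e.explanation_id in emap:
                raise ValidationError(
                    f"duplicate explanation_id {e.explanation_id!r}"
                )
            emap[e.explanation_id] = e
        kb = cls(findings=fmap, explanations=emap, associations=list(associations))
        kb.reindex()
        return kb

    def reindex(self) -> None:
        self.by_finding = {fid: [] for fid in self.findings}
        self.by_explanation = {eid: [] for eid in self.explanations}
        for a in self.associations:
            self.by_finding.setdefault(a.finding_id, []).append(a)
            self.by_explanation.setdefault(a.explanation_id, []).append(a)

    def weight(self, explanation_id: str, finding_id: str) -> float | None:
        """Weight of the (explanation, finding) pair, or None if unlinked."""
        for a in self.by_explanation.get(explanation_id, ()):
            if a.finding_id == finding_id:
                return a.weight
        return None

    def positive_findings(self, explanation_id: str) -> dict[str, float]:
        """finding_id -> weight for the positively weighted associations."""
        return {
            a.finding_id: a.weight
            for a in self.by_explanation.get(explanation_id, ())
            if a.weight > 0
        }

    def negated_findings(self, explanation_id: str) -> set[str]:
        return {
            a.finding_id
            for a in self.by_explanation.get(explanation_id, ())
            if a.weight == -1
        }


@dataclass(frozen=True)
class KbStats:
    """Shape summary of a knowledge base.

    ``findings_per_explanation`` is a histogram of positive-weight finding
    counts (bucket 0 holds explanations with no positive findings).
    Percentages are computed over diseases and medications jointly;
    ``pct_le5`` counts explanations described by one to five positive
    findings, so zero-finding entries lower it rather than inflate it.
    """

    n_findings: int
    n_explanations: int
    findings_per_explanation: dict[int, int]
    top_findings: list[tuple[str, int]]
    pct_le5: float
    pct_ge10: float
    pct_single: float


# ---------------------------------------------------------------------------
# Encoding conventions
# ---------------------------------------------------------------------------

def encode_frequency(description: str | float | int) -> float:
    """Map a frequency description to an association weight.

    Accepts a fraction in ``[0, 1]`` (returned exactly), a percentage string
    such as ``"10%"`` (value / 100), or a textual frequency term from
    :data:`TEXTUAL_WEIGHTS` (``"always"`` -> 1.0, ``"never"`` -> 0,
    ``"negating"`` -> -1, ...).

    Raises :class:`EncodingError` for unrecognized text or out-of-range
    numbers.
    """
    if isinstance(description, (int, float)) and not isinstance(description, bool):
        value = float(description)
        if 0.0 <= value <= 1.0:
            return value
        raise EncodingError(f"fraction out of range [0, 1]: {description!r}")
    if not isinstance(description, str):
        raise EncodingError(f"unrecognized frequency description: {description!r}")
    text = description.strip().lower()
    if not text:
        raise EncodingError("empty frequency description")
    if text in TEXTUAL_WEIGHTS:
        return TEXTUAL_WEIGHTS[text]
    if text.endswith("%"):
        try:
            pct = float(text[:-1])
        except ValueError:
            raise EncodingError(f"unparseable percentage: {description!r}") from None
        if 0.0 <= pct <= 100.0:
            return pct / 100.0
        raise EncodingError(f"percentage out of range [0, 100]: {description!r}")
    try:
        value = float(text)
    except ValueError:
        raise EncodingError(
            f"unrecognized frequency description: {description!r}"
        ) from None
    if 0.0 <= value <= 1.0:
        return value
    raise EncodingError(f"fraction out of range [0, 1]: {description!r}")


_MONTHS_PER_YEAR = 12
_CHILD_UPPER_MONTHS = 13 * _MONTHS_PER_YEAR   # child ends before the 13th year
_ADULT_UPPER_MONTHS = 61 * _MONTHS_PER_YEAR   # 60-year-olds are adults


def age_group_of(age_months: int) -> AgeGroup:
    """Total, gap-free mapping of age in months to a broad age group.

    Half-open buckets: infant [0, 6) months, child [6 months, 13 years),
    adult [13, 61) years, elderly [61 years, inf).
    """
    if age_months < 0:
        raise ValueError(f"age_months must be non-negative, got {age_months}")
    if age_months < 6:
        return AgeGroup.INFANT
    if age_months < _CHILD_UPPER_MONTHS:
        return AgeGroup.CHILD
    if age_months < _ADULT_UPPER_MONTHS:
        return AgeGroup.ADULT
    return AgeGroup.ELDERLY


def autocomplete(kb: KnowledgeBase, prefix: str, limit: int = 10) -> list[Finding]:
    """Findings whose label starts with ``prefix`` (case-insensitive).

    Exact prefix match only — no synonym expansion. Sorted by label then id,
    truncated to ``limit``.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    needle = prefix.lower()
    hits = [f for f in kb.findings.values() if f.label.lower().startswith(needle)]
    hits.sort(key=lambda f: (f.label, f.finding_id))
    return hits[:limit]


def kb_statistics(kb: KnowledgeBase, top_n: int = 10) -> KbStats:
    """Summary statistics over positive-weight associations only."""
    counts: dict[str, int] = {eid: 0 for eid in kb.explanations}
    per_finding: dict[str, int] = {}
    for a in kb.associations:
        if a.weight > 0:
            counts[a.explanation_id] = counts.get(a.explanation_id, 0) + 1
            per_finding[a.finding_id] = per_finding.get(a.finding_id, 0) + 1
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    n = len(kb.explanations)
    if n:
        le5 = sum(v for k, v in hist.items() if 1 <= k <= 5)
        ge10 = sum(v for k, v in hist.items() if k >= 10)
        single = hist.get(1, 0)
        pct_le5, pct_ge10, pct_single = (
            100.0 * le5 / n,
            100.0 * ge10 / n,
            100.0 * single / n,
        )
    else:
        pct_le5 = pct_ge10 = pct_single = 0.0
    top = sorted(per_finding.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return KbStats(
        n_findings=len(kb.findings),
        n_explanations=n,
        findings_per_explanation=hist,
        top_findings=top,
        pct_le5=pct_le5,
        pct_ge10=pct_ge10,
        pct_single=pct_single,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _legal_weight(w: float) -> bool:
    return w == -1.0 or 0.0 <= w <= 1.0


def validate(kb: KnowledgeBase) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid).

    Never raises: every problem is reported as a string naming the entity,
    the rule, and the offending value.
    """
    out: list[str] = []
    for fid, f in kb.findings.items():
        if not fid:
            out.append("finding: empty finding_id")
        if f.vocabulary in (Vocabulary.SNOMED, Vocabulary.LOINC) and not str(
            f.code
        ).strip():
            out.append(
                f"finding {fid}: vocabulary {f.vocabulary.value} requires a "
                "non-empty code"
            )
    for eid, e in kb.explanations.items():
        if not eid:
            out.append("explanation: empty explanation_id")
        if e.kind is ExplanationKind.DISEASE and e.code_system not in (
            CodeSystem.ICD10,
            CodeSystem.LOCAL,
        ):
            out.append(
                f"explanation {eid}: DISEASE must use ICD10 or LOCAL codes, "
                f"got {e.code_system.value}"
            )
        if e.kind is ExplanationKind.MEDICATION and e.code_system not in (
            CodeSystem.RXNORM,
            CodeSystem.LOCAL,
        ):
            out.append(
                f"explanation {eid}: MEDICATION must use RXNORM or LOCAL "
                f"codes, got {e.code_system.value}"
            )
        if e.code_system is not CodeSystem.LOCAL and not str(e.code).strip():
            out.append(
                f"explanation {eid}: code_system {e.code_system.value} "
                "requires a non-empty code"
            )
    seen_pairs: set[tuple[str, str]] = set()
    for a in kb.associations:
        pair = (a.explanation_id, a.finding_id)
        if pair in seen_pairs:
            out.append(
                f"association ({a.explanation_id}, {a.finding_id}): "
                "duplicate pair"
            )
        seen_pairs.add(pair)
        if a.explanation_id not in kb.explanations:
            out.append(
                f"association ({a.explanation_id}, {a.finding_id}): "
                f"unknown explanation_id {a.explanation_id!r}"
            )
        if a.finding_id not in kb.findings:
            out.append(
                f"association ({a.explanation_id}, {a.finding_id}): "
                f"unknown finding_id {a.finding_id!r}"
            )
        if not _legal_weight(a.weight):
            out.append(
                f"association ({a.explanation_id}, {a.finding_id}): "
                f"illegal weight {a.weight}"
            )
    indexed = sorted(
        (a.explanation_id, a.finding_id, a.weight)
        for assocs in kb.by_explanation.values()
        for a in assocs
    )
    listed = sorted((a.explanation_id, a.finding_id, a.weight) for a in kb.associations)
    if indexed != listed:
        out.append("index: by_explanation index inconsistent with association list")
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FINDING_COLS = ["finding_id", "label", "vocabulary", "code"]
_EXPLANATION_COLS = [
    "explanation_id",
    "label",
    "kind",
    "code_system",
    "code",
    "regions",
    "age_groups",
    "sex",
]
_ASSOCIATION_COLS = ["explanation_id", "finding_id", "weight"]

_TABLE_FILES = {
    "findings": "findings.csv",
    "explanations": "explanations.csv",
    "associations": "associations.csv",
}


def _format_weight(w: float) -> str:
    """Canonical textual form: '-1' for negations, shortest repr otherwise."""
    if w == -1.0:
        return "-1"
    return repr(float(w))


def _split_tags(cell: str) -> list[str]:
    return [t for t in str(cell).split(";") if t]


def _parse_weight(raw: str, *, strict: bool, where: str) -> float:
    try:
        w = float(raw)
    except (TypeError, ValueError):
        raise SchemaError(f"{where}: unparseable weight {raw!r}") from None
    if _legal_weight(w):
        return w
    if strict:
        raise ValidationError(f"{where}: illegal weight {w}")
    if -1.0 <= w <= 1.0:
        # Lenient repair: clamp to the nearest legal value (0 or -1).
        clamped = -1.0 if w < -0.5 else 0.0
        import logging

        logging.getLogger(__name__).warning(
            "%s: clamped illegal weight %s to %s", where, w, clamped
        )
        return clamped
    raise ValidationError(f"{where}: weight {w} outside [-1, 1], not repairable")


def _rows_from_kb(kb: KnowledgeBase) -> dict[str, list[list[str]]]:
    frows = [
        [f.finding_id, f.label, f.vocabulary.value, f.code]
        for f in sorted(kb.findings.values(), key=lambda f: f.finding_id)
    ]
    erows = [
        [
            e.explanation_id,
            e.label,
            e.kind.value,
            e.code_system.value,
            e.code,
            ";".join(sorted(e.regions)),
            ";".join(sorted(g.value for g in e.age_groups)),
            e.sex.value,
        ]
        for e in sorted(kb.explanations.values(), key=lambda e: e.explanation_id)
    ]
    arows = [
        [a.explanation_id, a.finding_id, _format_weight(a.weight)]
        for a in sorted(
            kb.associations, key=lambda a: (a.explanation_id, a.finding_id)
        )
    ]
    return {"findings": frows, "explanations": erows, "associations": arows}


def save_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the canonical dialect: a CSV directory, or YAML if ``path`` ends
    in ``.yaml``/``.yml``.  Output is byte-stable (sorted rows, fixed number
    format); ``load(save(kb))`` reproduces an equivalent knowledge base."""
    path = Path(path)
    rows = _rows_from_kb(kb)
    try:
        if path.suffix in (".yaml", ".yml"):
            doc = {
                "findings": [dict(zip(_FINDING_COLS, r)) for r in rows["findings"]],
                "explanations": [
                    dict(zip(_EXPLANATION_COLS, r)) for r in rows["explanations"]
                ],
                "associations": [
                    dict(zip(_ASSOCIATION_COLS, r)) for r in rows["associations"]
                ],
            }
            path.parent.mkdir(parents=True, exist_ok=True)
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
            return
        path.mkdir(parents=True, exist_ok=True)
        headers = {
            "findings": _FINDING_COLS,
            "explanations": _EXPLANATION_COLS,
            "associations": _ASSOCIATION_COLS,
        }
        for table, fname in _TABLE_FILES.items():
            buf = io.StringIO()
            w = csv.writer(buf, lineterminator="\n")
            w.writerow(headers[table])
            w.writerows(rows[table])
            (path / fname).write_text(buf.getvalue(), encoding="utf-8")
    except OSError as exc:
        raise LoadError(f"cannot write knowledge base to {path}: {exc}") from exc


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise LoadError(f"missing table file: {path}")
    df = pd.read_csv(path, dtype=str, na_filter=False)
    unknown = [c for c in df.columns if c not in columns]
    missing = [c for c in columns if c not in df.columns]
    if unknown or missing:
        raise SchemaError(
            f"{path}: unexpected columns {unknown}, missing columns {missing}"
        )
    return df


def _kb_from_frames(
    fdf: pd.DataFrame,
    edf: pd.DataFrame,
    adf: pd.DataFrame,
    *,
    strict: bool,
    source: str,
) -> KnowledgeBase:
    try:
        findings = [
            Finding(
                finding_id=r.finding_id,
                label=r.label,
                vocabulary=Vocabulary(r.vocabulary),
                code=r.code,
            )
            for r in fdf.itertuples()
        ]
        explanations = [
            Explanation(
                explanation_id=r.explanation_id,
                label=r.label,
                kind=ExplanationKind(r.kind),
                code_system=CodeSystem(r.code_system),
                code=r.code,
                regions=frozenset(_split_tags(r.regions)),
                age_groups=frozenset(AgeGroup(g) for g in _split_tags(r.age_groups)),
                sex=Sex(r.sex),
            )
            for r in edf.itertuples()
        ]
    except ValueError as exc:
        raise SchemaError(f"{source}: bad enum value ({exc})") from exc
    associations = [
        Association(
            explanation_id=r.explanation_id,
            finding_id=r.finding_id,
            weight=_parse_weight(
                r.weight,
                strict=strict,
                where=(
                    f"{source} associations row {i + 2} "
                    f"({r.explanation_id}, {r.finding_id})"
                ),
            ),
        )
        for i, r in enumerate(adf.itertuples())
    ]
    kb = KnowledgeBase.build(findings, explanations, associations)
    dangling = sorted(
        {a.explanation_id for a in associations if a.explanation_id not in kb.explanations}
        | {a.finding_id for a in associations if a.finding_id not in kb.findings}
    )
    if dangling:
        raise IntegrityError(
            f"{source}: associations reference unknown ids: {', '.join(dangling)}"
        )
    violations = validate(kb)
    if violations:
        raise ValidationError(f"{source}: " + "; ".join(violations))
    return kb


def load_knowledge_base(path: str | Path, strict: bool = True) -> KnowledgeBase:
    """Load a knowledge base from a CSV directory or a single YAML file.

    In strict mode any invariant violation aborts the load.  In lenient mode
    weights outside ``[0, 1] ∪ {-1}`` but within ``[-1, 1]`` are clamped to
    the nearest legal value and logged; every other violation still aborts.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such knowledge base: {path}")
    if path.is_file() and path.suffix in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        frames = {}
        for table, cols in (
            ("findings", _FINDING_COLS),
            ("explanations", _EXPLANATION_COLS),
            ("associations", _ASSOCIATION_COLS),
        ):
            rows = doc.get(table)
            if rows is None:
                raise SchemaError(f"{path}: missing section {table!r}")
            frames[table] = pd.DataFrame(rows, columns=cols).fillna("").astype(str)
        return _kb_from_frames(
            frames["findings"],
            frames["explanations"],
            frames["associations"],
            strict=strict,
            source=str(path),
        )
    if path.is_dir():
        fdf = _read_table(path / _TABLE_FILES["findings"], _FINDING_COLS)
        edf = _read_table(path / _TABLE_FILES["explanations"], _EXPLANATION_COLS)
        adf = _read_table(path / _TABLE_FILES["associations"], _ASSOCIATION_COLS)
        return _kb_from_frames(fdf, edf, adf, strict=strict, source=str(path))
    raise LoadError(f"not a knowledge-base directory or YAML file: {path}")
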