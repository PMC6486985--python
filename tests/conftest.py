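"""Shared fixtures: the shipped toy knowledge base and random instances."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pytest

from dxcover.diagnosis import PatientCase
from dxcover.kb import (
    Association,
    Explanation,
    Finding,
    KnowledgeBase,
    load_knowledge_base,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_kb_path() -> Path:
    return DATA_DIR / "toy_kb"


@pytest.fixture(scope="session")
def toy_manifest() -> dict:
    return json.loads((DATA_DIR / "toy_kb_manifest.json").read_text())


@pytest.fixture()
def toy_kb(toy_kb_path) -> KnowledgeBase:
    return load_knowledge_base(toy_kb_path)


def make_kb(weights: dict[str, dict[str, float]], **explanation_kwargs) -> KnowledgeBase:
    """Build a KB from {explanation_id: {finding_id: weight}} in one line.

    ``explanation_kwargs`` maps explanation_id -> dict of Explanation field
    overrides (regions, age_groups, sex, ...).
    """
    finding_ids = sorted({f for ws in weights.values() for f in ws})
    findings = [Finding(finding_id=f, label=f"finding {f}") for f in finding_ids]
    explanations = [
        Explanation(
            explanation_id=e, label=f"explanation {e}", **explanation_kwargs.get(e, {})
        )
        for e in sorted(weights)
    ]
    associations = [
        Association(explanation_id=e, finding_id=f, weight=w)
        for e, ws in sorted(weights.items())
        for f, w in sorted(ws.items())
    ]
    return KnowledgeBase.build(findings, explanations, associations)


def random_instance(
    rng: np.random.Generator,
    n_explanations: int = 8,
    n_findings: int = 10,
    density: float = 0.4,
) -> tuple[KnowledgeBase, PatientCase]:
    """A random weighted set-cover instance plus a case observing a random
    non-empty subset of findings."""
    weights: dict[str, dict[str, float]] = {}
    for i in range(n_explanations):
        eid = f"D{i:02d}"
        ws = {
            f"S{j:02d}": float(np.round(rng.uniform(0.05, 1.0), 2))
            for j in range(n_findings)
            if rng.random() < density
        }
        weights[eid] = ws
    # ensure every finding id exists even if unlinked
    all_findings = {f"S{j:02d}": 0 for j in range(n_findings)}
    for eid in weights:
        if not weights[eid]:
            weights[eid] = {f"S{int(rng.integers(n_findings)):02d}": 0.5}
    kb = make_kb(weights)
    for fid in all_findings:
        if fid not in kb.findings:
            kb.findings[fid] = Finding(finding_id=fid, label=f"finding {fid}")
    kb.reindex()
    n_obs = int(rng.integers(1, n_findings + 1))
    observed = frozenset(
        f"S{j:02d}" for j in rng.choice(n_findings, size=n_obs, replace=False)
    )
    case = PatientCase(case_id="random", observed=observed)
    return kb, case
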