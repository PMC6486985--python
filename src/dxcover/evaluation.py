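"""Benchmark protocol: Top-n buckets, utility scoring, summaries, Wilcoxon.

A diagnostic run is recorded per case and tool as the rank of the correct
diagnosis in the returned list (or a miss).  Ranks are grouped into nested
Top-1 / Top-10 / Top-20 buckets and mapped to a utility score in {3, 2, 1, 0}
(Top1 → 3, Top10 → 2, Top20 → 1, miss → 0).  Tools are compared per group by
the percentage of Top-1 hits, the cumulative percentage of Top-20 hits, and
the mean utility score, with paired score differences tested by the Wilcoxon
signed-rank test.

The signed-rank test is implemented here with an exact null distribution
(shift convolution over midranks, equivalent to enumerating all 2^n sign
assignments) used automatically for up to 25 non-zero differences, and a
tie-corrected, continuity-corrected normal approximation beyond that.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import LoadError, SchemaError

__all__ = [
    "MISS",
    "Bucket",
    "EvaluationRecord",
    "SummaryRow",
    "WilcoxonResult",
    "bucket_of",
    "load_records",
    "pairwise_wilcoxon",
    "render_summary",
    "save_records",
    "summarize",
    "utility_score",
    "wilcoxon_signed_rank",
]

#: Sentinel for "correct diagnosis absent from the returned list".
MISS = None

_EXACT_MAX_N = 25


class Bucket(str, enum.Enum):
    TOP1 = "TOP1"
    TOP10 = "TOP10"
    TOP20 = "TOP20"
    MISS = "MISS"


_BUCKET_SCORE = {Bucket.TOP1: 3, Bucket.TOP10: 2, Bucket.TOP20: 1, Bucket.MISS: 0}


@dataclass(frozen=True)
class EvaluationRecord:
    """(case, tool, dataset, rank-of-correct-diagnosis); rank None = miss."""

    case_id: str
    tool: str
    dataset: str
    rank: int | None


@dataclass(frozen=True)
class SummaryRow:
    """One group (tool × dataset) of the comparison table.

    ``pct_top20`` is cumulative: it includes Top-1 and Top-10 hits.
    """

    group: tuple[str, ...]
    n_cases: int
    pct_top1: float
    pct_top20: float
    mean_score: float


@dataclass(frozen=True)
class WilcoxonResult:
    n_nonzero: int
    statistic: float
    z_value: float
    p_value: float
    method: str  # "EXACT" | "NORMAL_APPROX"
    degenerate: bool = False


def _check_rank(rank: int | None) -> None:
    if rank is not None and rank < 1:
        raise ValueError(f"rank must be >= 1 or MISS (None), got {rank}")


def bucket_of(rank: int | None) -> Bucket:
    """Innermost Top-n bucket of a rank: 1 → TOP1, 2–10 → TOP10,
    11–20 → TOP20, beyond 20 or missing → MISS."""
    _check_rank(rank)
    if rank is None or rank > 20:
        return Bucket.MISS
    if rank == 1:
        return Bucket.TOP1
    if rank <= 10:
        return Bucket.TOP10
    return Bucket.TOP20


def utility_score(rank: int | None) -> int:
    """Map rank of the correct explanation to the 0–3 utility score."""
    return _BUCKET_SCORE[bucket_of(rank)]


def summarize(
    records: Iterable[EvaluationRecord],
    group_by: Sequence[str] = ("tool", "dataset"),
) -> list[SummaryRow]:
    """One SummaryRow per group.

    ``group_by`` is a subset of {"tool", "dataset"}; an empty subset yields a
    single overall row.  Percentages and mean scores are exact; rounding
    happens only in :func:`render_summary`.
    """
    records = list(records)
    if not records:
        raise ValueError("summarize requires at least one record")
    bad = set(group_by) - {"tool", "dataset"}
    if bad:
        raise ValueError(f"group_by may only contain 'tool'/'dataset', got {bad}")
    df = pd.DataFrame(
        {
            "tool": [r.tool for r in records],
            "dataset": [r.dataset for r in records],
            "bucket": [bucket_of(r.rank) for r in records],
            "score": [utility_score(r.rank) for r in records],
        }
    )
    keys = list(group_by)
    grouped = df.groupby(keys, sort=True) if keys else [((), df)]
    rows: list[SummaryRow] = []
    for name, sub in grouped:
        if keys and not isinstance(name, tuple):
            name = (name,)
        n = len(sub)
        top1 = int((sub["bucket"] == Bucket.TOP1).sum())
        in20 = int(sub["bucket"].isin([Bucket.TOP1, Bucket.TOP10, Bucket.TOP20]).sum())
        rows.append(
            SummaryRow(
                group=tuple(name),
                n_cases=n,
                pct_top1=100.0 * top1 / n,
                pct_top20=100.0 * in20 / n,
                mean_score=float(sub["score"].mean()),
            )
        )
    return rows


def render_summary(rows: Sequence[SummaryRow]) -> str:
    """Plain-text table: integer percents, scores to two decimals."""
    out = ["group\tn\ttop1\ttop20\tscore"]
    for r in rows:
        label = "/".join(r.group) if r.group else "all"
        out.append(
            f"{label}\t{r.n_cases}\t{round(r.pct_top1)}%\t"
            f"{round(r.pct_top20)}%\t{r.mean_score:.2f}"
        )
    return "\n".join(out)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _exact_sf_leq(doubled_ranks: np.ndarray, doubled_stat: int) -> float:
    """P(W+ <= stat) for the exact null, via shift convolution.

    ``doubled_ranks`` are midranks times two (integers even with ties), so
    the distribution of the doubled positive-rank sum lives on integers.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    return float(dist[: doubled_stat + 1].sum())


def wilcoxon_signed_rank(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are discarded (classic treatment); absolute differences
    are midranked.  The statistic is the smaller of the positive- and
    negative-signed rank sums.  The exact null distribution is used when at
    most 25 non-zero differences remain; otherwise a normal approximation
    with tie-corrected variance and a 0.5 continuity correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scores_a and scores_b must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            n_nonzero=0, statistic=0.0, z_value=0.0, p_value=1.0,
            method="EXACT", degenerate=True,
        )
    ranks = rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts ** 3 - tie_counts) / 48.0).sum()
    )
    if var > 0:
        z = (stat - mean + 0.5) / np.sqrt(var)
    else:
        z = 0.0
    p_approx = min(1.0, 2.0 * float(norm.cdf(z)))

    if n <= _EXACT_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        p = min(1.0, 2.0 * _exact_sf_leq(doubled, int(round(2 * stat))))
        method = "EXACT"
    else:
        p = p_approx
        method = "NORMAL_APPROX"
    return WilcoxonResult(
        n_nonzero=n, statistic=stat, z_value=float(z), p_value=p, method=method
    )


def pairwise_wilcoxon(
    records: Iterable[EvaluationRecord],
) -> list[tuple[str, str, WilcoxonResult]]:
    """All tool-pair comparisons on per-case utility scores.

    Cases are paired by case id; only cases scored by both tools of a pair
    enter that comparison.
    """
    recs = list(records)
    scores: dict[str, dict[str, int]] = {}
    for r in recs:
        scores.setdefault(r.tool, {})[r.case_id] = utility_score(r.rank)
    tools = sorted(scores)
    out: list[tuple[str, str, WilcoxonResult]] = []
    for i, ta in enumerate(tools):
        for tb in tools[i + 1:]:
            common = sorted(set(scores[ta]) & set(scores[tb]))
            if len(common) < 2:
                continue
            res = wilcoxon_signed_rank(
                [scores[ta][c] for c in common],
                [scores[tb][c] for c in common],
            )
            out.append((ta, tb, res))
    return out


# ---------------------------------------------------------------------------
# Records I/O
# ---------------------------------------------------------------------------

_RECORD_COLS = ["case_id", "tool", "dataset", "rank"]


def load_records(path: str | Path) -> list[EvaluationRecord]:
    """Read a CSV of evaluation records; rank "NA" (or empty) means a miss."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such records file: {path}")
    df = pd.read_csv(path, dtype=str, na_filter=False)
    missing = [c for c in _RECORD_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out: list[EvaluationRecord] = []
    for i, r in enumerate(df.itertuples()):
        raw = str(r.rank).strip()
        if raw in ("", "NA", "na", "NaN"):
            rank: int | None = MISS
        else:
            try:
                rank = int(raw)
            except ValueError:
                raise SchemaError(
                    f"{path} line {i + 2}: unparseable rank {raw!r}"
                ) from None
            if rank < 1:
                raise SchemaError(f"{path} line {i + 2}: rank must be >= 1, got {rank}")
        out.append(
            EvaluationRecord(
                case_id=r.case_id, tool=r.tool, dataset=r.dataset, rank=rank
            )
        )
    return out


def save_records(records: Iterable[EvaluationRecord], path: str | Path) -> None:
    rows = [
        {
            "case_id": r.case_id,
            "tool": r.tool,
            "dataset": r.dataset,
            "rank": "NA" if r.rank is None else str(r.rank),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLS).to_csv(path, index=False)
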