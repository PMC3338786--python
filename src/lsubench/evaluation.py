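"""Benchmark metrics: recovery, erroneous recovery, coverage.

Per rank, over the queries whose true lineage names that rank:

* recovery            — proportion classified to the correct taxon;
* erroneous recovery  — proportion classified to a wrong taxon;
* coverage            — proportion classified at all (so coverage =
  recovery + erroneous recovery).

Queries whose truth lacks a rank are excluded from that rank's
denominator: a truth-side annotation gap is not the classifier's fault.
All three are reported as proportions so methods and datasets of
different sizes stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers.base import Assignment
from .taxonomy import (
    CORRECT, INCORRECT, RANKS, UNCLASSIFIED, Lineage, compare_at_rank,
)

__all__ = [
    "RankMetrics",
    "EvaluationSummary",
    "evaluate",
    "summaries_to_frame",
    "aggregate_sem",
    "track_error_degradation",
]


@dataclass(frozen=True)
class RankMetrics:
    """Counts at one rank; denominator n = queries whose truth names it."""

    n: int
    correct: int
    incorrect: int

    @property
    def unclassified(self) -> int:
        return self.n - self.correct - self.incorrect

    @property
    def recovery(self) -> float:
        return self.correct / self.n if self.n else float("nan")

    @property
    def erroneous(self) -> float:
        return self.incorrect / self.n if self.n else float("nan")

    @property
    def coverage(self) -> float:
        return (self.correct + self.incorrect) / self.n if self.n else float("nan")


@dataclass
class EvaluationSummary:
    """Per-rank metrics for one (method, primer, length, rate, scenario) cell."""

    per_rank: dict[str, RankMetrics]
    n_queries: int
    labels: dict[str, object] = field(default_factory=dict)

    def metric(self, rank: str, name: str) -> float:
        return getattr(self.per_rank[rank], name)


def evaluate(
    assignments: Sequence[Assignment],
    truths: Mapping[str, Lineage],
    ranks: Sequence[str] = RANKS,
    labels: Optional[Mapping[str, object]] = None,
) -> EvaluationSummary:
    """Score a batch of assignments against their true lineages."""
    for a in assignments:
        if a.query_id not in truths:
            raise KeyError(f"no truth for query {a.query_id!r}")
    per_rank: dict[str, RankMetrics] = {}
    for rank in ranks:
        n = correct = incorrect = 0
        for a in assignments:
            truth = truths[a.query_id]
            if not truth.has_rank(rank):
                continue
            n += 1
            status = compare_at_rank(a.lineage, truth, rank)
            if status == CORRECT:
                correct += 1
            elif status == INCORRECT:
                incorrect += 1
        per_rank[rank] = RankMetrics(n=n, correct=correct, incorrect=incorrect)
    return EvaluationSummary(per_rank=per_rank, n_queries=len(assignments),
                             labels=dict(labels or {}))


def summaries_to_frame(summaries: Iterable[EvaluationSummary]) -> pd.DataFrame:
    """Long-format frame: one row per (labels..., rank, metric)."""
    rows = []
    for s in summaries:
        for rank, m in s.per_rank.items():
            for metric in ("recovery", "erroneous", "coverage"):
                rows.append({**s.labels, "rank": rank, "metric": metric,
                             "value": getattr(m, metric), "n": m.n})
    return pd.DataFrame(rows)


def aggregate_sem(
    summaries: Sequence[EvaluationSummary],
    by: Sequence[str],
) -> pd.DataFrame:
    """Mean and standard error of the mean per grouping cell.

    SEM = sd/sqrt(n) over the summaries falling in each (by..., rank,
    metric) cell — e.g. grouping by method averages over primers, the
    way benchmark figures draw their error bars. Cells with a single
    summary get SEM = NaN and ``sem_defined`` False.
    """
    frame = summaries_to_frame(summaries)
    keys = list(by) + ["rank", "metric"]
    grouped = frame.groupby(keys, sort=False)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_cells="count")
    out["sem"] = out["sd"] / np.sqrt(out["n_cells"])
    out["sem_defined"] = out["n_cells"] >= 2
    return out.reset_index()


def track_error_degradation(
    assignments_by_rate: Mapping[float, Sequence[Assignment]],
    truths: Mapping[str, Lineage],
    rank: str = "genus",
) -> dict[float, float]:
    """Recovery change, per error rate, among queries correct at rate 0.

    delta(r) = (still-correct fraction of the tracked set at rate r) - 1,
    so delta(0) = 0 and deltas are non-positive by construction.
    """
    if 0 not in assignments_by_rate and 0.0 not in assignments_by_rate:
        raise ValueError("baseline (rate 0) results required")
    baseline = assignments_by_rate.get(0, assignments_by_rate.get(0.0))
    tracked = {
        a.query_id for a in baseline
        if truths[a.query_id].has_rank(rank)
        and compare_at_rank(a.lineage, truths[a.query_id], rank) == CORRECT
    }
    if not tracked:
        raise ValueError("no query correctly classified at rate 0")
    deltas: dict[float, float] = {}
    for rate, assignments in assignments_by_rate.items():
        still = sum(
            1 for a in assignments
            if a.query_id in tracked
            and compare_at_rank(a.lineage, truths[a.query_id], rank) == CORRECT
        )
        deltas[rate] = still / len(tracked) - 1.0
    return deltas
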