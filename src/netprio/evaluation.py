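"""Knockout-benchmark evaluation: ranks, pooled ROC/AUC, top-k counts,
error reduction.

Each benchmark case contributes one positive (the knockout gene) and
``n_d - 1`` negatives (the other candidates).  The ROC is pooled over cases
by a common rank threshold k = 0..max(n_d): a case is a true positive at
threshold k once its knockout ranks at or above k, and every other candidate
at rank <= k is a false positive.  For a single case the resulting AUC is
exactly the Mann-Whitney probability (n - r) / (n - 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .rankers import Ranking

__all__ = [
    "BenchmarkCase",
    "EvaluationReport",
    "rank_of_knockout",
    "pooled_roc_auc",
    "per_case_auc",
    "top_fraction_count",
    "error_reduction",
    "mean_rank",
    "evaluate_rankings",
]


@dataclass
class BenchmarkCase:
    """One knockout experiment: candidate list plus the true gene."""

    case_id: str
    candidates: tuple[str, ...]
    knockout: str

    def __post_init__(self) -> None:
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError(f"{self.case_id}: duplicate candidate ids")
        if self.knockout not in self.candidates:
            raise ValueError(f"{self.case_id}: knockout not among candidates")


def rank_of_knockout(ranking: Ranking, case: BenchmarkCase) -> int:
    """1-based position of the case's knockout gene in the ranking."""
    try:
        return ranking.rank_of(case.knockout)
    except KeyError:
        raise ValueError(
            f"{case.case_id}: knockout {case.knockout!r} absent from ranking"
        ) from None


def pooled_roc_auc(ranks: list[tuple[int, int]]) -> tuple[np.ndarray, float]:
    """Pooled ROC curve and AUC from per-case (rank, n_candidates) pairs.

    Thresholds sweep k = 0..max(n_d).  TPR(k) is the fraction of cases whose
    knockout ranks <= k; FPR(k) pools all non-knockout candidates ranked
    <= k over the total number of negatives.  AUC is the trapezoidal area.
    """
    if not ranks:
        raise ValueError("no ranks to evaluate")
    for r, n in ranks:
        if not 1 <= r <= n:
            raise ValueError(f"rank {r} outside 1..{n}")
    D = len(ranks)
    total_neg = sum(n - 1 for _, n in ranks)
    if total_neg == 0:
        raise ValueError("no negatives: every case has a single candidate")
    kmax = max(n for _, n in ranks)
    ks = np.arange(kmax + 1)
    tpr = np.empty(kmax + 1)
    fpr = np.empty(kmax + 1)
    for k in ks:
        hits = sum(1 for r, _ in ranks if r <= k)
        fp = sum(min(k, n) - (1 if r <= k else 0) for r, n in ranks)
        tpr[k] = hits / D
        fpr[k] = fp / total_neg
    auc = float(np.trapezoid(tpr, fpr))
    roc = np.column_stack([fpr, tpr])
    return roc, auc


def per_case_auc(ranks: list[tuple[int, int]]) -> float:
    """Mean of single-case AUCs (n - r) / (n - 1) — the averaged alternative
    to pooling."""
    if not ranks:
        raise ValueError("no ranks to evaluate")
    return float(np.mean([(n - r) / (n - 1) for r, n in ranks]))


def top_fraction_count(ranks: list[tuple[int, int]], fraction: float = 0.1) -> int:
    """Number of cases whose knockout ranks within the top ``fraction`` of
    its candidate list (boundary rank ceil(fraction * n) included)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return sum(1 for r, n in ranks if r <= int(np.ceil(fraction * n)))


def error_reduction(x_new: float, x_base: float, x_max: float) -> float:
    """Percent of the gap to the metric ceiling closed relative to a baseline:
    ``100 * (x_new - x_base) / (x_max - x_base)``.

    The ceiling is 1 for AUC and the number of cases for top-k counts.
    Negative values mean the new method did worse than the baseline.
    """
    if x_base >= x_max:
        raise ValueError("baseline already at or above the metric ceiling")
    return 100.0 * (x_new - x_base) / (x_max - x_base)


def mean_rank(ranks: list[tuple[int, int]] | list[int]) -> float:
    """Arithmetic mean of the knockout ranks."""
    if not ranks:
        raise ValueError("no ranks to average")
    rs = [r[0] if isinstance(r, tuple) else r for r in ranks]
    return float(np.mean(rs))


@dataclass
class EvaluationReport:
    """Aggregate benchmark result for one strategy."""

    strategy: str
    case_ranks: dict[str, tuple[int, int]]
    roc: np.ndarray = field(repr=False)
    auc: float = 0.0
    mean_rank: float = 0.0
    top10_count: int = 0
    top20_count: int = 0
    error_reduction_vs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "case_ranks": {c: list(rn) for c, rn in self.case_ranks.items()},
            "roc": self.roc.tolist(),
            "auc": self.auc,
            "mean_rank": self.mean_rank,
            "top10_count": self.top10_count,
            "top20_count": self.top20_count,
            "error_reduction_vs": self.error_reduction_vs,
        }

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def evaluate_rankings(
    rankings: dict[str, Ranking],
    cases: dict[str, BenchmarkCase],
    strategy: str = "",
    baseline: "EvaluationReport | None" = None,
) -> EvaluationReport:
    """Score one strategy's rankings over a set of benchmark cases.

    If ``baseline`` is given, error reductions of the AUC and top-10% count
    relative to it are included (ceilings 1 and the number of cases).
    """
    if set(rankings) != set(cases):
        raise ValueError("rankings and cases cover different case ids")
    case_ranks = {
        cid: (rank_of_knockout(rankings[cid], cases[cid]), len(rankings[cid]))
        for cid in sorted(cases)
    }
    pairs = list(case_ranks.values())
    roc, auc = pooled_roc_auc(pairs)
    report = EvaluationReport(
        strategy=strategy,
        case_ranks=case_ranks,
        roc=roc,
        auc=auc,
        mean_rank=mean_rank(pairs),
        top10_count=top_fraction_count(pairs, 0.1),
        top20_count=top_fraction_count(pairs, 0.2),
    )
    if baseline is not None:
        D = len(pairs)
        report.error_reduction_vs = {
            "baseline": baseline.strategy,
            "auc": error_reduction(auc, baseline.auc, 1.0),
            "top10": error_reduction(report.top10_count, baseline.top10_count, D),
        }
    return report
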