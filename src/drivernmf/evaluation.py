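"""Evaluation against benchmark driver-gene lists.

Precision–recall curves are swept over every cutoff rank r = 1..p of a
ranking, with TP counted against the benchmark genes present in the scored
universe (benchmark genes outside the universe are undiscoverable by
construction and are dropped from the positives).  Enrichment of a top-k
candidate set is the one-sided Fisher's exact test, i.e. the hypergeometric
upper tail P(overlap ≥ observed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import hypergeom

from .io import BenchmarkGeneSet
from .scoring import RankedGeneList

__all__ = [
    "PRCurve",
    "EnrichmentResult",
    "precision_recall",
    "pr_auc",
    "fisher_enrichment",
    "overlap_counts",
]


@dataclass
class PRCurve:
    """Precision/recall at every cutoff rank, plus the positive count."""

    recall: np.ndarray
    precision: np.ndarray
    positives: int

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recall.tolist(), self.precision.tolist()))


@dataclass
class EnrichmentResult:
    """One-sided Fisher's exact enrichment of a candidate set."""

    cutoff: int
    overlap: int
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def precision_recall(
    ranking: RankedGeneList, benchmark: BenchmarkGeneSet
) -> PRCurve:
    """PR curve of a ranking against a benchmark list.

    At cutoff rank r: precision = TP/r and recall = TP/positives where TP is
    the number of benchmark genes among the top r and positives is the number
    of benchmark genes in the ranked universe.
    """
    universe = ranking.gene_ids
    pos_set = benchmark.genes & set(universe)
    if not pos_set:
        raise ValueError(
            f"benchmark {benchmark.name!r} shares no genes with the ranking"
        )
    hits = np.fromiter((g in pos_set for g in universe), dtype=float)
    tp = np.cumsum(hits)
    ranks = np.arange(1, len(universe) + 1, dtype=float)
    return PRCurve(
        recall=tp / len(pos_set), precision=tp / ranks, positives=len(pos_set)
    )


def pr_auc(curve: PRCurve, method: str = "trapezoid") -> float:
    """Area under the PR curve over the recall axis.

    ``trapezoid`` (default) integrates the rank-swept points with a
    (recall=0, precision@rank-1) anchor; duplicated-recall runs contribute
    zero width.  ``average_precision`` sums precision at each new-positive
    rank weighted by the recall increment.
    """
    if method == "trapezoid":
        rec = np.concatenate(([0.0], curve.recall))
        prec = np.concatenate(([curve.precision[0]], curve.precision))
        return float(np.trapezoid(prec, rec))
    if method == "average_precision":
        drec = np.diff(np.concatenate(([0.0], curve.recall)))
        return float(np.sum(drec * curve.precision))
    raise ValueError(f"unknown AUC method {method!r}")


def fisher_enrichment(
    candidates: BenchmarkGeneSet | set,
    benchmark: BenchmarkGeneSet,
    universe: list[str],
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher's exact test of candidates vs benchmark.

    The 2×2 table partitions the universe by candidate and benchmark
    membership; the p-value is the hypergeometric upper tail
    P(X ≥ overlap) for X ~ Hypergeom(N=|universe|, K=positives, n=|candidates|).
    """
    cand = candidates.genes if isinstance(candidates, BenchmarkGeneSet) else set(candidates)
    uni = set(universe)
    if not cand:
        raise ValueError("candidate set is empty")
    if not cand <= uni:
        raise ValueError("candidate genes must lie within the universe")
    pos = benchmark.genes & uni
    N, n, K = len(uni), len(cand), len(pos)
    overlap = len(cand & pos)
    p = float(hypergeom.sf(overlap - 1, N, K, n))
    table = (
        (overlap, n - overlap),
        (K - overlap, N - n - K + overlap),
    )
    return EnrichmentResult(
        cutoff=n, overlap=overlap, p_value=min(p, 1.0), table=table
    )


def overlap_counts(
    rankings: list[RankedGeneList], k: int
) -> dict[frozenset, int]:
    """Venn-style partition counts of the rankings' top-k sets.

    For every non-empty subset S of methods, the value is the number of genes
    whose top-k membership is exactly S; counts sum to |union of top-k sets|.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    universes = [frozenset(r.gene_ids) for r in rankings]
    if any(u != universes[0] for u in universes):
        raise ValueError("rankings are over different gene universes")
    labels = [r.method_label or f"method{i}" for i, r in enumerate(rankings)]
    if len(set(labels)) != len(labels):
        raise ValueError("method labels must be distinct")
    tops = {
        lab: {g for g, _ in r.entries[:k]} for lab, r in zip(labels, rankings)
    }
    union = set().union(*tops.values())
    counts: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for subset in combinations(labels, r):
            counts[frozenset(subset)] = 0
    for g in union:
        membership = frozenset(lab for lab in labels if g in tops[lab])
        counts[membership] += 1
    return counts
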