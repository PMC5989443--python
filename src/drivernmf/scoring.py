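"""Gene scoring and ranking: max-coefficient mutation scores and the
mutation-frequency baseline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BenchmarkGeneSet, MutationMatrix

__all__ = [
    "RankedGeneList",
    "gene_scores",
    "rank_genes",
    "mutation_frequency_scores",
    "top_k",
]


@dataclass
class RankedGeneList:
    """Genes in non-increasing score order."""

    entries: list[tuple[str, float]]
    method_label: str = ""

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("ranked gene list contains duplicate gene ids")
        scores = [s for _, s in self.entries]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing down the ranking")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])


def gene_scores(V: np.ndarray, gene_ids: list[str] | None = None) -> np.ndarray:
    """Mutation score per gene: the maximum coefficient across latent
    dimensions, score_j = max_k V_{jk}."""
    V = np.asarray(V)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D gene-by-dimension matrix")
    if gene_ids is not None and len(gene_ids) != V.shape[0]:
        raise ValueError(
            f"{len(gene_ids)} gene ids for {V.shape[0]} gene representations"
        )
    return V.max(axis=1)


def mutation_frequency_scores(mut: MutationMatrix) -> np.ndarray:
    """Baseline score: the number of samples in which each gene is mutated."""
    return np.asarray(mut.X).sum(axis=0).astype(float)


def rank_genes(
    scores: np.ndarray,
    gene_ids: list[str],
    tiebreak_freq: np.ndarray | None = None,
    method_label: str = "",
) -> RankedGeneList:
    """Stable descending sort by score; ties broken by higher mutation
    frequency, then lexicographic gene id (deterministic under input
    permutation)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(gene_ids):
        raise ValueError(f"{len(scores)} scores for {len(gene_ids)} gene ids")
    if tiebreak_freq is not None and len(tiebreak_freq) != len(gene_ids):
        raise ValueError("tiebreak frequency vector length mismatch")
    freq = (
        np.zeros(len(gene_ids))
        if tiebreak_freq is None
        else np.asarray(tiebreak_freq, dtype=float)
    )
    order = sorted(
        range(len(gene_ids)),
        key=lambda j: (-scores[j], -freq[j], gene_ids[j]),
    )
    return RankedGeneList(
        entries=[(gene_ids[j], float(scores[j])) for j in order],
        method_label=method_label,
    )


def top_k(ranking: RankedGeneList, k: int = 200) -> BenchmarkGeneSet:
    """The first k ranked genes as a candidate driver set."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    return BenchmarkGeneSet(
        name=f"{ranking.method_label or 'ranking'}_top{k}",
        genes={g for g, _ in ranking.entries[:k]},
    )
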