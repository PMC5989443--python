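"""Readers, writers and alignment for the on-disk artifacts.

All tabular formats are plain TSV.  Matrices carry a header row of gene
identifiers and a first column of sample identifiers; networks are two-column
edge lists (extra columns ignored, ``#`` comments skipped); benchmark gene
lists hold one identifier per line.  Identifier matching is case-sensitive
throughout and no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "MutationMatrix",
    "ExpressionMatrix",
    "GeneNetwork",
    "BenchmarkGeneSet",
    "AlignedDataset",
    "read_mutation_matrix",
    "read_expression_matrix",
    "read_network_edgelist",
    "read_gene_list",
    "read_ranking",
    "align_datasets",
    "write_mutation_matrix",
    "write_expression_matrix",
    "write_network_edgelist",
    "write_gene_list",
    "write_ranking",
]


class LoadError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


def _check_unique(ids: Sequence[str], kind: str, path) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise LoadError(f"duplicate {kind} identifier {x!r} in {path}")
        seen.add(x)


@dataclass
class MutationMatrix:
    """Binary somatic-mutation indicator matrix X (n samples × p genes)."""

    sample_ids: list[str]
    gene_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.gene_ids)}) identifiers"
            )
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("mutation matrix entries must be exactly 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


@dataclass
class ExpressionMatrix:
    """Real-valued mRNA expression matrix (n samples × g genes), assumed
    normalized upstream."""

    sample_ids: list[str]
    gene_ids: list[str]
    E: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.E.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.gene_ids)}) identifiers"
            )
        if not np.isfinite(self.E).all():
            raise ValueError("expression matrix contains non-finite entries")


@dataclass
class GeneNetwork:
    """Undirected gene interaction graph as a set of unordered id pairs.

    Self-loops are stripped and edges deduplicated at construction; isolated
    genes may appear in ``gene_ids`` with no incident edge.
    """

    gene_ids: list[str]
    edges: set[frozenset]

    def __post_init__(self) -> None:
        known = set(self.gene_ids)
        clean: set[frozenset] = set()
        for e in self.edges:
            pair = frozenset(e)
            if len(pair) != 2:
                continue  # self-loop
            a, b = pair
            if a not in known or b not in known:
                raise ValueError(f"edge endpoint outside gene universe: {sorted(pair)}")
            clean.add(pair)
        self.edges = clean

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class BenchmarkGeneSet:
    """Named set of curated benchmark driver genes (e.g. CGC, IntOGen)."""

    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"benchmark gene set {self.name!r} is empty")


@dataclass
class AlignedDataset:
    """Mutation, expression and network data on common sample/gene universes.

    Samples are the intersection of the mutation and expression cohorts in
    mutation-file order; the gene universe is the mutation matrix's gene list
    (expression genes are untouched — they only feed sample correlation).
    """

    mutation: MutationMatrix
    expression: ExpressionMatrix
    network: GeneNetwork
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers


def _read_matrix_frame(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    _check_unique(list(df.index.astype(str)), "sample", path)
    _check_unique(list(df.columns.astype(str)), "gene", path)
    return df


def read_mutation_matrix(path) -> MutationMatrix:
    """Load a binary sample-by-gene mutation matrix from TSV."""
    df = _read_matrix_frame(path)
    values = df.to_numpy()
    bad = ~np.isin(values, ("0", "1"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise LoadError(
            f"non-binary cell {values[i, j]!r} at sample {df.index[i]!r}, "
            f"gene {df.columns[j]!r} in {path}"
        )
    return MutationMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        X=values.astype(np.int8),
    )


def read_expression_matrix(path) -> ExpressionMatrix:
    """Load a real-valued sample-by-gene expression matrix from TSV."""
    df = _read_matrix_frame(path)
    values = df.to_numpy()
    try:
        E = values.astype(float)
    except ValueError as exc:
        raise LoadError(f"non-numeric expression cell in {path}: {exc}") from exc
    if not np.isfinite(E).all():
        i, j = np.argwhere(~np.isfinite(E))[0]
        raise LoadError(
            f"non-finite expression value at sample {df.index[i]!r}, "
            f"gene {df.columns[j]!r} in {path}"
        )
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        E=E,
    )


def read_network_edgelist(path) -> GeneNetwork:
    """Load an undirected edge list (2+ whitespace-separated columns).

    Lines starting with ``#`` and blank lines are skipped; self-loops are
    stripped and duplicate edges (in either orientation) collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    gene_ids: list[str] = []
    seen: set[str] = set()
    edges: set[frozenset] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise LoadError(f"malformed edge at {path}:{lineno}: {line!r}")
            a, b = cols[0], cols[1]
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    gene_ids.append(g)
            if a != b:
                edges.add(frozenset((a, b)))
    return GeneNetwork(gene_ids=gene_ids, edges=edges)


def read_gene_list(path, name: str | None = None) -> BenchmarkGeneSet:
    """Load a benchmark gene list (one identifier per line, blanks ignored)."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    genes = {line.strip() for line in open(path) if line.strip()}
    if not genes:
        raise LoadError(f"gene list {path} is empty")
    return BenchmarkGeneSet(name=name or path.stem, genes=genes)


def read_ranking(path):
    """Load a ranking TSV written by :func:`write_ranking`."""
    from .scoring import RankedGeneList

    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("rank", "gene_id", "score"):
        if col not in df.columns:
            raise LoadError(f"ranking file {path} lacks column {col!r}")
    entries = [(str(g), float(s)) for g, s in zip(df["gene_id"], df["score"])]
    return RankedGeneList(entries=entries, method_label=path.stem)


# ---------------------------------------------------------------------------
# alignment


def align_datasets(
    mut: MutationMatrix, expr: ExpressionMatrix, net: GeneNetwork
) -> AlignedDataset:
    """Place the three inputs on common sample and gene universes.

    Samples become the mutation∩expression intersection in mutation-file
    order; the gene universe is the mutation gene list, with network edges
    restricted to it (genes without edges are kept as isolated nodes so that
    every mutated gene receives a score).
    """
    expr_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    shared = [s for s in mut.sample_ids if s in expr_pos]
    if not shared:
        raise ValueError("no samples shared between mutation and expression data")

    mut_keep = [i for i, s in enumerate(mut.sample_ids) if s in expr_pos]
    mut2 = MutationMatrix(
        sample_ids=shared, gene_ids=list(mut.gene_ids), X=mut.X[mut_keep, :]
    )
    expr2 = ExpressionMatrix(
        sample_ids=shared,
        gene_ids=list(expr.gene_ids),
        E=expr.E[[expr_pos[s] for s in shared], :],
    )
    universe = set(mut.gene_ids)
    kept_edges = {e for e in net.edges if e <= universe}
    net2 = GeneNetwork(gene_ids=list(mut.gene_ids), edges=kept_edges)
    provenance = {
        "mutation_samples_dropped": mut.n_samples - len(shared),
        "expression_samples_dropped": len(expr.sample_ids) - len(shared),
        "network_edges_dropped": len(net.edges) - len(kept_edges),
        "network_genes_dropped": len(set(net.gene_ids) - universe),
    }
    return AlignedDataset(
        mutation=mut2, expression=expr2, network=net2, provenance=provenance
    )


# ---------------------------------------------------------------------------
# writers


def _write_matrix(path, sample_ids, gene_ids, M, fmt: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(gene_ids) + "\n")
        for s, row in zip(sample_ids, M):
            fh.write(s + "\t" + "\t".join(fmt % v for v in row) + "\n")


def write_mutation_matrix(path, mat: MutationMatrix) -> None:
    _write_matrix(path, mat.sample_ids, mat.gene_ids, mat.X, "%d")


def write_expression_matrix(path, mat: ExpressionMatrix) -> None:
    _write_matrix(path, mat.sample_ids, mat.gene_ids, mat.E, "%.10g")


def write_network_edgelist(path, net: GeneNetwork) -> None:
    """Write edges sorted for byte-stable output; isolated genes are listed
    in a trailing comment block so the gene universe round-trips."""
    touched: set[str] = set()
    for e in net.edges:
        touched |= e
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")
        for g in net.gene_ids:
            if g not in touched:
                fh.write(f"# isolated\t{g}\n")


def write_gene_list(path, genes: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def write_ranking(path, ranking) -> None:
    """Write a ranking as TSV (rank, gene_id, score), 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tscore\n")
        for r, (g, s) in enumerate(ranking.entries, start=1):
            fh.write(f"{r}\t{g}\t{s:.6g}\n")
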