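"""Prior structures: expression-derived sample similarity and network Laplacians.

Two priors regularize the factorization.  On the sample side, pairwise
expression correlation ρ between tumour samples is mapped through a Gaussian
kernel W = exp{−(1−ρ)²/(2σ²)} whose un-normalized Laplacian L_W = D_W − W
smooths the sample representations.  On the gene side, the interaction
network adjacency A is symmetrically normalized, Â = D_A^{−1/2} A D_A^{−1/2},
giving the normalized Laplacian L̂ = I − Â; the corresponding normalized
degree matrix reduces to the identity, which is how it enters the updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlignedDataset, ExpressionMatrix, GeneNetwork

__all__ = [
    "SampleSimilarity",
    "NetworkPriors",
    "PriorsBundle",
    "sample_correlation",
    "similarity_from_correlation",
    "build_network_priors",
    "laplacian",
    "build_priors",
]


@dataclass
class SampleSimilarity:
    """Gaussian similarity kernel over samples with its degree and Laplacian.

    W is symmetric with unit diagonal and entries in (0, 1]; L_W = D_W − W is
    left un-normalized.
    """

    W: np.ndarray
    D_W: np.ndarray
    L_W: np.ndarray
    sigma: float
    rho: np.ndarray


@dataclass
class NetworkPriors:
    """Gene-network adjacency with symmetric normalization.

    ``A_hat`` rows/columns of degree-0 genes are all zero (the D_A^{−1/2}
    scaling factor is defined as 0 there); ``D_hat`` is the identity.
    """

    A: np.ndarray
    D_A: np.ndarray
    A_hat: np.ndarray
    L_hat: np.ndarray
    D_hat: np.ndarray


@dataclass
class PriorsBundle:
    sample: SampleSimilarity
    gene: NetworkPriors


def sample_correlation(expr: ExpressionMatrix, method: str = "pearson") -> np.ndarray:
    """Pairwise correlation between sample expression profiles.

    Parameters
    ----------
    expr
        Expression matrix; every gene shared by the matrix contributes.
    method
        ``"pearson"`` (default) or ``"spearman"``.

    Raises
    ------
    ValueError
        If fewer than two genes are present or a sample profile is constant
        (its correlation is undefined; erroring beats fabricating similarity).
    """
    E = expr.E
    if E.shape[1] < 2:
        raise ValueError("need at least 2 expression genes to correlate samples")
    sd = E.std(axis=1)
    if (sd == 0).any():
        bad = expr.sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"constant expression profile for sample {bad!r}")
    if method == "spearman":
        from scipy.stats import rankdata

        E = rankdata(E, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    rho = np.corrcoef(E)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def similarity_from_correlation(rho: np.ndarray, sigma: float = 1.0) -> SampleSimilarity:
    """Map a correlation matrix through the Gaussian kernel
    W_ij = exp{−|1−ρ_ij|²/(2σ²)}.

    σ is the bandwidth controlling how fast similarity falls off with
    decorrelation; W has unit diagonal and strictly positive entries.
    """
    if sigma <= 0:
        raise ValueError(f"bandwidth sigma must be positive, got {sigma}")
    rho = np.asarray(rho, dtype=float)
    W = np.exp(-np.abs(1.0 - rho) ** 2 / (2.0 * sigma**2))
    np.fill_diagonal(W, 1.0)
    D, L = laplacian(W)
    return SampleSimilarity(W=W, D_W=D, L_W=L, sigma=float(sigma), rho=rho)


def laplacian(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix and (un-normalized) graph Laplacian D − S of a symmetric
    nonnegative similarity matrix S."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"expected square matrix, got shape {S.shape}")
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    D = np.diag(S.sum(axis=1))
    return D, D - S


def build_network_priors(net: GeneNetwork, gene_ids: list[str]) -> NetworkPriors:
    """Assemble A, D_A, Â = D_A^{−1/2} A D_A^{−1/2} and L̂ = I − Â in
    ``gene_ids`` order.  Degree-0 genes get zero rows/columns in Â and the
    normalized degree matrix is the identity."""
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids contain duplicates")
    pos = {g: i for i, g in enumerate(gene_ids)}
    p = len(gene_ids)
    A = np.zeros((p, p))
    for e in net.edges:
        a, b = tuple(e)
        if a not in pos or b not in pos:
            raise ValueError(f"network edge {sorted(e)} outside gene universe")
        i, j = pos[a], pos[b]
        A[i, j] = A[j, i] = 1.0
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(deg > 0, deg**-0.5, 0.0)
    A_hat = dinv_sqrt[:, None] * A * dinv_sqrt[None, :]
    return NetworkPriors(
        A=A,
        D_A=np.diag(deg),
        A_hat=A_hat,
        L_hat=np.eye(p) - A_hat,
        D_hat=np.eye(p),
    )


def build_priors(
    data: AlignedDataset, sigma: float = 1.0, method: str = "pearson"
) -> PriorsBundle:
    """Convenience: both priors from an aligned dataset."""
    rho = sample_correlation(data.expression, method=method)
    sample = similarity_from_correlation(rho, sigma=sigma)
    gene = build_network_priors(data.network, data.mutation.gene_ids)
    return PriorsBundle(sample=sample, gene=gene)
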