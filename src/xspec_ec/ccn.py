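"""Conserved co-expression network (CCN) node identification.

A background distribution of Pearson correlations is built per species
from random gene pairs; a pair of reference orthologs {i, j} is a
conserved edge when its intra-species co-expression exceeds the chosen
background quantile in BOTH species (strict inequality), and the CCN
nodes — the Essien reference set — are all genes incident to at least one
conserved edge.  Raising the quantile can only shrink the node set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix, ValidationError
from .coexpr_ec import PCM

__all__ = [
    "BackgroundDistribution",
    "CCNNodes",
    "background_correlations",
    "correlation_threshold",
    "identify_ccn_nodes",
]


@dataclass
class BackgroundDistribution:
    """Empirical intra-species correlation distribution from random pairs."""

    samples: np.ndarray
    n_pairs: int
    seed: int
    species_tag: str = ""
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and (
            self.samples.min() < -1 - 1e-9 or self.samples.max() > 1 + 1e-9
        ):
            raise ValidationError("background correlations must lie in [-1, 1]")
        if self.samples.size + self.n_degenerate != self.n_pairs:
            raise ValidationError("background sample count does not reconcile with n_pairs")


@dataclass
class CCNNodes:
    """CCN node set with the thresholds that produced it."""

    node_indices: set[int]
    threshold_A: float
    threshold_B: float
    quantile_x: float
    n_conserved_edges: int


def background_correlations(
    M: ExpressionMatrix, n_pairs: int = 20000, seed: int = 0, species_tag: str = ""
) -> BackgroundDistribution:
    """Correlations of ``n_pairs`` random ordered gene pairs (i, j), i != j.

    Pairs are drawn uniformly with replacement; draws involving a constant
    profile (correlation undefined) are skipped and counted.
    """
    if M.n_genes < 2:
        raise ValidationError("background needs at least 2 genes")
    if M.n_conditions < 3:
        raise ValidationError("background needs at least 3 conditions")
    if n_pairs < 0:
        raise ValidationError("n_pairs must be nonnegative")
    X = M.values
    sd = X.std(axis=1)
    if int((sd > 0).sum()) < 2:
        raise ValidationError("fewer than 2 non-constant genes")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, M.n_genes, size=n_pairs)
    j = rng.integers(0, M.n_genes - 1, size=n_pairs)
    j = j + (j >= i)  # uniform over j != i
    ok = (sd[i] > 0) & (sd[j] > 0)
    n_degenerate = int((~ok).sum())
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    r = (Z[i[ok]] * Z[j[ok]]).sum(axis=1) / M.n_conditions
    return BackgroundDistribution(
        samples=np.clip(r, -1.0, 1.0),
        n_pairs=n_pairs,
        seed=seed,
        species_tag=species_tag,
        n_degenerate=n_degenerate,
    )


def correlation_threshold(bg: BackgroundDistribution, x: float) -> float:
    """Empirical x-quantile of the background (linear interpolation)."""
    if bg.samples.size == 0:
        raise ValidationError("background distribution is empty")
    if not 0 <= x <= 1:
        raise ValidationError("quantile must lie in [0, 1]")
    return float(np.quantile(bg.samples, x, method="linear"))


def identify_ccn_nodes(
    pcm_A: PCM, pcm_B: PCM, thr_A: float, thr_B: float, x: float
) -> CCNNodes:
    """All-pairs scan for conserved co-expression.

    Edge {i, j} (i != j) is conserved iff ``pcm_A[i, j] > thr_A`` and
    ``pcm_B[i, j] > thr_B`` (strictly).  Nodes are genes with at least one
    conserved edge.
    """
    if pcm_A.k != pcm_B.k or not np.array_equal(pcm_A.gene_index, pcm_B.gene_index):
        raise ValidationError("PCMs are not aligned")
    E = (pcm_A.values > thr_A) & (pcm_B.values > thr_B)
    np.fill_diagonal(E, False)
    E = E | E.T  # edge criterion is symmetric; guard asymmetric inputs
    n_edges = int(np.triu(E, k=1).sum())
    nodes = set(int(i) for i in np.flatnonzero(E.any(axis=1)))
    return CCNNodes(
        node_indices=nodes,
        threshold_A=float(thr_A),
        threshold_B=float(thr_B),
        quantile_x=float(x),
        n_conserved_edges=n_edges,
    )
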