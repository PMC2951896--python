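"""Distribution summaries, null controls and method-agreement analyses.

Two negative controls probe whether a method detects non-random
conservation of orthologs:

* random gene pairs — a uniformly sampled permutation pi of the B-side
  indices pairs gene i of species A with gene pi(i) of species B (fixed
  points are permitted and logged; about one is expected at realistic k);
* permuted reference orthology — the columns of the reference-side PCM
  are shuffled so that reference position j no longer corresponds to
  ortholog j, destroying the cross-species meaning of the reference set
  while keeping each row's value distribution intact.

Agreement between methods is quantified by Pearson and Spearman
correlations over the pairs valid under both methods (complete cases);
the same machinery applies to Euclidean divergences.  The whole-data vs
common-tissue comparison rebuilds PCMs on each condition panel and
contrasts the two EC distributions with Welch's two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .data_io import PairedExpression, ValidationError
from .preprocess import subset_tissues
from .tissue_ec import ECResult, liao_zhang_ec
from .coexpr_ec import PCM, pairwise_correlation_matrix, dutilh_ec, icc, essien_ec

logger = logging.getLogger("xspec_ec")

__all__ = [
    "DistributionSummary",
    "AgreementResult",
    "SubsetComparison",
    "summarize_ec",
    "compute_ec",
    "random_pair_ec",
    "permute_reference_orthology",
    "method_agreement",
    "compare_tissue_subsets",
    "distance_vs_ec_agreement",
]

COEXPR_METHODS = ("dutilh", "icc", "essien")
ALL_METHODS = ("liao_zhang",) + COEXPR_METHODS


@dataclass
class DistributionSummary:
    """Mean / sample-sd summary of one EC distribution."""

    method: str
    population: str
    mean: float
    sd: float
    n_valid: int


@dataclass
class AgreementResult:
    """Pearson + Spearman agreement between two score vectors."""

    method_pair: tuple[str, str]
    pearson_r: float
    spearman_rho: float
    n_pairs_used: int


@dataclass
class SubsetComparison:
    """Whole-data vs common-tissue EC comparison for one method."""

    method: str
    full: ECResult
    common: ECResult
    t_statistic: float
    p_value: float
    agreement: AgreementResult


def summarize_ec(ec: ECResult, population_label: str) -> DistributionSummary:
    """Mean and sample standard deviation over valid ECs only."""
    vals = ec.valid_ec()
    if vals.size < 2:
        raise ValidationError("need at least 2 valid ECs to summarize")
    return DistributionSummary(
        method=ec.method,
        population=population_label,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n_valid=int(vals.size),
    )


def compute_ec(
    method: str,
    *,
    paired: Optional[PairedExpression] = None,
    pcm_A: Optional[PCM] = None,
    pcm_B: Optional[PCM] = None,
    node_indices: Optional[Iterable[int]] = None,
    pairing: Optional[Sequence[int]] = None,
    **method_kwargs,
) -> ECResult:
    """Dispatch one EC method with a uniform calling convention.

    The tissue method needs ``paired`` (already restricted to common
    tissues); the co-expression methods need the two PCMs (and a node set
    for ``"essien"``).  ``pairing`` re-pairs the B side for the
    random-pair null.
    """
    if method == "liao_zhang":
        if paired is None:
            raise ValidationError("liao_zhang needs paired expression over common tissues")
        if pairing is not None:
            p = np.asarray(pairing, dtype=int)
            paired = PairedExpression(paired.matrix_A, paired.matrix_B.take_genes(p))
        return liao_zhang_ec(paired)
    if pcm_A is None or pcm_B is None:
        raise ValidationError(f"{method} needs pcm_A and pcm_B")
    if method == "dutilh":
        return dutilh_ec(pcm_A, pcm_B, pairing=pairing, **method_kwargs)
    if method == "icc":
        result, _ = icc(pcm_A, pcm_B, pairing=pairing, **method_kwargs)
        return result
    if method == "essien":
        if node_indices is None:
            raise ValidationError("essien needs a CCN node set")
        return essien_ec(pcm_A, pcm_B, node_indices, pairing=pairing)
    raise ValidationError(f"unknown method {method!r}")


def random_pair_ec(
    method: str,
    seed: int,
    *,
    paired: Optional[PairedExpression] = None,
    pcm_A: Optional[PCM] = None,
    pcm_B: Optional[PCM] = None,
    node_indices: Optional[Iterable[int]] = None,
    permutation: Optional[Sequence[int]] = None,
    **method_kwargs,
) -> ECResult:
    """EC of random cross-species gene pairs (permutation null).

    A uniform permutation pi of 0..k-1 pairs A-gene i with B-gene pi(i);
    the method's reference machinery is untouched (reference orthology is
    NOT shuffled).  ``permutation`` forces a specific pairing (identity
    reproduces the ortholog ECs exactly).
    """
    if paired is not None:
        k = paired.k
    elif pcm_A is not None:
        k = pcm_A.k
    else:
        raise ValidationError("random_pair_ec needs paired expression or PCMs")
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(k)
    p = np.asarray(permutation, dtype=int)
    n_fixed = int((p == np.arange(k)).sum())
    if n_fixed:
        logger.info("random_pair_ec: permutation has %d fixed points", n_fixed)
    result = compute_ec(
        method,
        paired=paired,
        pcm_A=pcm_A,
        pcm_B=pcm_B,
        node_indices=node_indices,
        pairing=p,
        **method_kwargs,
    )
    result.params.update({"population": "random_pairs", "seed": seed, "n_fixed_points": n_fixed})
    return result


def permute_reference_orthology(
    pcm_B: PCM, seed: int, permutation: Optional[Sequence[int]] = None
) -> PCM:
    """Column-permute the reference-side PCM (negative control).

    Row identity is preserved, but reference position j of every B-row no
    longer corresponds to ortholog j.  The output is generally asymmetric
    and is valid only as the reference-side input of an EC computation.
    """
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(pcm_B.k)
    p = np.asarray(permutation, dtype=int)
    if sorted(p.tolist()) != list(range(pcm_B.k)):
        raise ValidationError("permutation must be a permutation of 0..k-1")
    return PCM(
        pcm_B.values[:, p],
        gene_index=pcm_B.gene_index.copy(),
        symmetric=bool(np.array_equal(p, np.arange(pcm_B.k))),
        params={**pcm_B.params, "reference_permuted": True, "seed": seed},
    )


def _joint_scores(r1: ECResult, r2: ECResult, use: str) -> tuple[np.ndarray, np.ndarray]:
    v1 = getattr(r1, use)
    v2 = getattr(r2, use)
    if v1 is None or v2 is None:
        raise ValidationError(f"both results must carry a {use} vector")
    if r1.k != r2.k:
        raise ValidationError("results have different lengths")
    both = r1.valid & r2.valid & np.isfinite(v1) & np.isfinite(v2)
    return v1[both], v2[both]


def method_agreement(ec1: ECResult, ec2: ECResult, use: str = "ec") -> AgreementResult:
    """Pearson and Spearman agreement over jointly valid pairs.

    Spearman uses average ranks for ties.  Raises when fewer than 3
    complete cases remain or either vector is constant.
    """
    x, y = _joint_scores(ec1, ec2, use)
    if x.size < 3:
        raise ValidationError("fewer than 3 jointly valid pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("agreement undefined: a score vector is constant")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return AgreementResult(
        method_pair=(ec1.method, ec2.method),
        pearson_r=pearson,
        spearman_rho=spearman,
        n_pairs_used=int(x.size),
    )


def distance_vs_ec_agreement(r1: ECResult, r2: ECResult) -> AgreementResult:
    """Agreement between two Euclidean-divergence vectors (same machinery
    as :func:`method_agreement`, applied to distances)."""
    return method_agreement(r1, r2, use="distance")


def compare_tissue_subsets(
    paired: PairedExpression,
    common_A: list[str],
    common_B: list[str],
    method: str,
    node_quantile_nodes: Optional[Iterable[int]] = None,
    common_node_indices: Optional[Iterable[int]] = None,
    **method_kwargs,
) -> SubsetComparison:
    """Contrast a co-expression method on all conditions vs common tissues.

    PCMs are built twice — from each species' full condition panel, and
    from the common-tissue columns only — and the two EC distributions are
    compared with Welch's (unequal-variance) two-sample t-test plus the
    paired Pearson/Spearman agreement of the two EC vectors.  ``node_*``
    arguments supply the CCN reference sets for the Essien variant
    (derived from the matching condition panel).
    """
    if method not in COEXPR_METHODS:
        raise ValidationError(f"method must be one of {COEXPR_METHODS}")
    pcm_A_full = pairwise_correlation_matrix(paired.matrix_A)
    pcm_B_full = pairwise_correlation_matrix(paired.matrix_B)
    sub = subset_tissues(paired, common_A, common_B)
    pcm_A_common = pairwise_correlation_matrix(sub.matrix_A)
    pcm_B_common = pairwise_correlation_matrix(sub.matrix_B)
    ec_full = compute_ec(
        method,
        pcm_A=pcm_A_full,
        pcm_B=pcm_B_full,
        node_indices=node_quantile_nodes,
        **method_kwargs,
    )
    ec_common = compute_ec(
        method,
        pcm_A=pcm_A_common,
        pcm_B=pcm_B_common,
        node_indices=common_node_indices if common_node_indices is not None else node_quantile_nodes,
        **method_kwargs,
    )
    a = ec_full.valid_ec()
    b = ec_common.valid_ec()
    if a.size < 2 or b.size < 2:
        raise ValidationError("too few valid ECs for the t-test")
    t = stats.ttest_ind(a, b, equal_var=False)
    agreement = method_agreement(ec_full, ec_common)
    ec_full.method = f"{method}_full"
    ec_common.method = f"{method}_common"
    return SubsetComparison(
        method=method,
        full=ec_full,
        common=ec_common,
        t_statistic=float(t.statistic),
        p_value=float(t.pvalue),
        agreement=agreement,
    )
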