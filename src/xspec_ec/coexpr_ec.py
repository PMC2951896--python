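"""Co-expression reference-set methods for expression conservation.

Each species' expression matrix (rows = the k 1-1 reference orthologs) is
first converted to a k x k pairwise correlation matrix (PCM) of Pearson
correlations between gene profiles over that species' own conditions.  Row
i of a PCM is gene i's co-expression fingerprint against the reference
set, and it is directly comparable across species because the reference
positions are orthologs.  Conservation scores:

* whole-ortholog-set EC (Dutilh): Pearson correlation of row i of PCM_A
  with row i of PCM_B over reference positions j != i;
* iterative comparison of co-expression (ICC, Tirosh & Barkai): the same
  correlation, but weighted, with each reference ortholog j weighted by
  its own EC from the previous iteration, iterated to convergence — so
  conserved orthologs dominate the reference and fast-evolving ones are
  down-weighted;
* CCN-restricted EC (Essien): the plain correlation restricted to the
  reference orthologs that are nodes of conserved co-expression networks;
* co-expression divergence: the Euclidean distance between the two rows
  over the chosen reference positions.

The diagonal entry of each PCM is structurally 1 and carries no
cross-species information, so self positions are excluded from every
reference-row comparison by default.  All reference sums run in ascending
index order, so restricted variants reduce *exactly* to the full ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_io import ExpressionMatrix, ValidationError
from .tissue_ec import ECResult

__all__ = [
    "UndefinedCorrelationError",
    "PCM",
    "ICCState",
    "pairwise_correlation_matrix",
    "weighted_pearson",
    "dutilh_ec",
    "icc",
    "essien_ec",
    "coexpr_distance",
]


class UndefinedCorrelationError(ValueError):
    """Weighted correlation is undefined (zero weighted variance)."""


@dataclass
class PCM:
    """k x k pairwise Pearson correlation matrix over the reference orthologs.

    ``gene_index`` holds the ortholog-pair indices (0-based) shared between
    the two species' PCMs.  ``symmetric`` is False only for derived
    matrices (e.g. a column-permuted reference-side PCM used as a negative
    control), which are valid only as the reference-side input of an EC
    computation.
    """

    values: np.ndarray
    gene_index: np.ndarray = None  # type: ignore[assignment]
    symmetric: bool = True
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("PCM must be square")
        if self.gene_index is None:
            self.gene_index = np.arange(self.values.shape[0])
        self.gene_index = np.asarray(self.gene_index, dtype=int)
        if self.gene_index.shape != (self.values.shape[0],):
            raise ValidationError("gene_index length must equal PCM dimension")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("PCM entries must be finite")
        if self.values.size and (self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9):
            raise ValidationError("PCM entries must lie in [-1, 1]")
        if self.symmetric:
            if not np.allclose(self.values, self.values.T, atol=1e-12):
                raise ValidationError("PCM is not symmetric")
            if not np.allclose(np.diag(self.values), 1.0):
                raise ValidationError("PCM diagonal must be 1")

    @property
    def k(self) -> int:
        return int(self.values.shape[0])


@dataclass
class ICCState:
    """Snapshot of one ICC iteration (for convergence auditing)."""

    ec_current: np.ndarray
    weights: np.ndarray
    iteration: int
    max_delta: float
    converged: bool


def pairwise_correlation_matrix(M: ExpressionMatrix) -> PCM:
    """Pearson correlations between all gene-profile pairs of one species.

    Requires >= 3 conditions and no constant rows (run
    :func:`xspec_ec.preprocess.drop_zero_variance` upstream); the diagonal
    is set to exactly 1.
    """
    if M.n_conditions < 3:
        raise ValidationError("PCM needs at least 3 conditions")
    if M.n_genes < 2:
        raise ValidationError("PCM needs at least 2 genes")
    spans = np.ptp(M.values, axis=1)
    if np.any(spans == 0):
        bad = M.gene_ids[int(np.flatnonzero(spans == 0)[0])]
        raise ValidationError(
            f"constant expression profile for gene {bad!r}; run drop_zero_variance first"
        )
    C = np.corrcoef(M.values)
    C = (C + C.T) / 2.0  # corrcoef is symmetric only to rounding; make it exact
    np.fill_diagonal(C, 1.0)
    return PCM(np.clip(C, -1.0, 1.0), params={"n_conditions": M.n_conditions})


def weighted_pearson(x: Sequence[float], y: Sequence[float], w: Sequence[float]) -> float:
    """Weighted product-moment correlation of two vectors.

    Weights are normalized to sum 1; weighted means, covariance and
    variances follow the definitional sums.  With uniform weights this is
    the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != y.shape or x.shape != w.shape or x.ndim != 1:
        raise ValidationError("x, y, w must be equal-length vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    sw = w.sum()
    if sw <= 0:
        raise ValidationError("weights must not be all zero")
    wn = w / sw
    mx = float(wn @ x)
    my = float(wn @ y)
    dx = x - mx
    dy = y - my
    cov = float(wn @ (dx * dy))
    varx = float(wn @ (dx * dx))
    vary = float(wn @ (dy * dy))
    support = w > 0
    if varx <= 0 or vary <= 0 or _is_constant(x, support) or _is_constant(y, support):
        raise UndefinedCorrelationError("zero weighted variance")
    return float(np.clip(cov / np.sqrt(varx * vary), -1.0, 1.0))


def _is_constant(v: np.ndarray, support: np.ndarray) -> bool:
    vv = v[support]
    return vv.size == 0 or vv.max() == vv.min()


# ---------------------------------------------------------------------------
# row-wise weighted EC core (shared by Dutilh / ICC / Essien and the nulls)
# ---------------------------------------------------------------------------


def _rowwise_weighted_ec(RA: np.ndarray, RB: np.ndarray, W: np.ndarray):
    """Weighted Pearson correlation of RA[i] vs RB[i] per row, weights W[i].

    Positions with weight 0 are excluded; a row is invalid when fewer than
    3 positions carry weight or either restricted vector is constant.
    Returns ``(ec, valid)`` with NaN at invalid rows.
    """
    k = RA.shape[0]
    support = W > 0
    n_support = support.sum(axis=1)
    sw = W.sum(axis=1)
    valid = n_support >= 3
    safe = np.where(sw > 0, sw, 1.0)
    Wn = W / safe[:, None]
    mx = (Wn * RA).sum(axis=1)
    my = (Wn * RB).sum(axis=1)
    dx = RA - mx[:, None]
    dy = RB - my[:, None]
    cov = (Wn * dx * dy).sum(axis=1)
    varx = (Wn * dx * dx).sum(axis=1)
    vary = (Wn * dy * dy).sum(axis=1)
    hi = np.where(support, RA, -np.inf).max(axis=1)
    lo = np.where(support, RA, np.inf).min(axis=1)
    const_x = hi == lo
    hi = np.where(support, RB, -np.inf).max(axis=1)
    lo = np.where(support, RB, np.inf).min(axis=1)
    const_y = hi == lo
    valid &= ~const_x & ~const_y & (varx > 0) & (vary > 0)
    ec = np.full(k, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(varx * vary)
    ec[valid] = np.clip(r[valid], -1.0, 1.0)
    return ec, valid


def _check_aligned(pcm_A: PCM, pcm_B: PCM) -> int:
    if pcm_A.k != pcm_B.k:
        raise ValidationError(f"PCM dimensions differ ({pcm_A.k} vs {pcm_B.k})")
    if not np.array_equal(pcm_A.gene_index, pcm_B.gene_index):
        raise ValidationError("PCM gene indices differ")
    if pcm_A.k < 3:
        raise ValidationError("need at least 3 reference orthologs")
    return pcm_A.k


def _reference_weights(
    k: int,
    node_indices: Optional[Iterable[int]],
    pairing: Optional[np.ndarray],
    row_weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Build the k x k weight matrix encoding reference set + self-exclusion."""
    if node_indices is None:
        base = np.ones(k)
    else:
        nodes = np.asarray(sorted(set(int(i) for i in node_indices)), dtype=int)
        if nodes.size and (nodes.min() < 0 or nodes.max() >= k):
            raise ValidationError("node indices out of range")
        if nodes.size < 4:
            raise ValidationError("reference set too small (need at least 4 nodes)")
        base = np.zeros(k)
        base[nodes] = 1.0
    if row_weights is not None:
        base = base * row_weights
    W = np.tile(base, (k, 1))
    idx = np.arange(k)
    W[idx, idx] = 0.0
    if pairing is not None:
        W[idx, pairing] = 0.0
    return W


def _resolve_pairing(k: int, pairing: Optional[Sequence[int]]) -> Optional[np.ndarray]:
    if pairing is None:
        return None
    p = np.asarray(pairing, dtype=int)
    if sorted(p.tolist()) != list(range(k)):
        raise ValidationError("pairing must be a permutation of 0..k-1")
    return p


def dutilh_ec(
    pcm_A: PCM,
    pcm_B: PCM,
    exclude_self: bool = True,
    pairing: Optional[Sequence[int]] = None,
) -> ECResult:
    """Whole-ortholog-set EC: correlate matching PCM rows across species.

    ``pairing`` (a permutation of 0..k-1) correlates row i of PCM_A with
    row pairing[i] of PCM_B instead — the random-gene-pair null; the
    excluded self positions are then {i, pairing[i]}.
    """
    k = _check_aligned(pcm_A, pcm_B)
    p = _resolve_pairing(k, pairing)
    RB = pcm_B.values if p is None else pcm_B.values[p, :]
    if exclude_self:
        W = _reference_weights(k, None, p)
    else:
        W = np.ones((k, k))
    ec, valid = _rowwise_weighted_ec(pcm_A.values, RB, W)
    return ECResult(
        method="dutilh",
        ec=ec,
        distance=None,
        valid=valid,
        params={"exclude_self": exclude_self, "paired_randomly": p is not None},
    )


def essien_ec(
    pcm_A: PCM,
    pcm_B: PCM,
    node_indices: Iterable[int],
    pairing: Optional[Sequence[int]] = None,
) -> ECResult:
    """CCN-restricted EC: like the whole-set EC but the reference positions
    are limited to conserved co-expression network nodes (minus the query
    gene itself when it is a node)."""
    k = _check_aligned(pcm_A, pcm_B)
    p = _resolve_pairing(k, pairing)
    RB = pcm_B.values if p is None else pcm_B.values[p, :]
    nodes = sorted(set(int(i) for i in node_indices))
    W = _reference_weights(k, nodes, p)
    ec, valid = _rowwise_weighted_ec(pcm_A.values, RB, W)
    return ECResult(
        method="essien",
        ec=ec,
        distance=None,
        valid=valid,
        params={"n_nodes": len(nodes), "paired_randomly": p is not None},
    )


def icc(
    pcm_A: PCM,
    pcm_B: PCM,
    tol: float = 1e-3,
    max_iter: int = 100,
    weight_floor: float = 0.0,
    weight_scheme: str = "clamp",
    pairing: Optional[Sequence[int]] = None,
) -> tuple[ECResult, list[ICCState]]:
    """Iterative comparison of co-expression.

    Iteration 0 uses uniform weights (identical to the whole-set EC).
    Each later iteration weights reference ortholog j by its EC from the
    previous iteration and recomputes every EC as a weighted correlation.
    Weight schemes map a previous EC to a nonnegative weight:

    * ``"clamp"`` (default): ``max(EC, weight_floor)`` — negative ECs get
      no influence;
    * ``"shifted"``: ``(EC + 1) / 2`` — affine map onto [0, 1];
    * ``"raw"``: the EC itself, negative values floored at 0 (raw negative
      weights would make the weighted correlation ill-defined).

    Invalid ECs always receive weight 0.  Iteration stops when the largest
    absolute EC change drops below ``tol`` (max-norm) or at ``max_iter``.
    Returns the final scores plus the per-iteration history.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    if weight_scheme not in ("clamp", "shifted", "raw"):
        raise ValidationError(f"unknown weight scheme {weight_scheme!r}")
    k = _check_aligned(pcm_A, pcm_B)
    p = _resolve_pairing(k, pairing)
    RB = pcm_B.values if p is None else pcm_B.values[p, :]

    W0 = _reference_weights(k, None, p)
    ec_prev, valid_prev = _rowwise_weighted_ec(pcm_A.values, RB, W0)
    history = [
        ICCState(ec_prev.copy(), np.ones(k), iteration=0, max_delta=np.inf, converged=False)
    ]
    converged = False
    for it in range(1, max_iter + 1):
        w = _weights_from_ec(ec_prev, valid_prev, weight_scheme, weight_floor)
        if w.sum() <= 0:
            raise ValidationError("ICC weight collapse: all reference weights are zero")
        W = _reference_weights(k, None, p, row_weights=w)
        ec_new, valid_new = _rowwise_weighted_ec(pcm_A.values, RB, W)
        if not np.array_equal(valid_new, valid_prev):
            max_delta = np.inf
        else:
            both = valid_new & valid_prev
            max_delta = float(np.abs(ec_new[both] - ec_prev[both]).max()) if both.any() else 0.0
        converged = max_delta < tol
        history.append(ICCState(ec_new.copy(), w, it, max_delta, converged))
        ec_prev, valid_prev = ec_new, valid_new
        if converged:
            break
    result = ECResult(
        method="icc",
        ec=ec_prev,
        distance=None,
        valid=valid_prev,
        params={
            "iterations": history[-1].iteration,
            "converged": converged,
            "tol": tol,
            "max_iter": max_iter,
            "weight_scheme": weight_scheme,
            "weight_floor": weight_floor,
            "final_max_delta": history[-1].max_delta,
            "paired_randomly": p is not None,
        },
    )
    return result, history


def _weights_from_ec(
    ec: np.ndarray, valid: np.ndarray, scheme: str, floor: float
) -> np.ndarray:
    w = np.zeros_like(ec)
    if scheme == "clamp":
        w[valid] = np.maximum(ec[valid], floor)
    elif scheme == "shifted":
        w[valid] = (ec[valid] + 1.0) / 2.0
    else:  # raw (negatives still floored at 0 to keep weights admissible)
        w[valid] = np.maximum(ec[valid], 0.0)
    return np.maximum(w, 0.0)


def coexpr_distance(
    pcm_A: PCM,
    pcm_B: PCM,
    node_indices: Optional[Iterable[int]] = None,
    pairing: Optional[Sequence[int]] = None,
) -> ECResult:
    """Euclidean distance between matching PCM rows over the reference set.

    The reference positions are all j != i, or the CCN nodes when
    ``node_indices`` is given (mirroring the EC variants).
    """
    k = _check_aligned(pcm_A, pcm_B)
    p = _resolve_pairing(k, pairing)
    RB = pcm_B.values if p is None else pcm_B.values[p, :]
    W = _reference_weights(k, None if node_indices is None else node_indices, p)
    support = W > 0
    diff = np.where(support, pcm_A.values - RB, 0.0)
    dist = np.sqrt((diff**2).sum(axis=1))
    valid = support.sum(axis=1) >= 1
    dist[~valid] = np.nan
    return ECResult(
        method="coexpr_distance" if node_indices is None else "coexpr_distance_ccn",
        ec=None,
        distance=dist,
        valid=valid,
        params={"restricted": node_indices is not None, "paired_randomly": p is not None},
    )
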