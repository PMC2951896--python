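"""Corresponding-tissue expression conservation (Liao & Zhang style).

Each gene's profile over the n corresponding tissues is normalized to
relative abundance (RA) — the expression in each tissue divided by the
gene's summed expression over the panel — which removes per-gene and
per-platform scale.  Expression conservation (EC) for ortholog pair i is
the Pearson correlation of the two RA vectors; the divergence counterpart
is the Euclidean distance between them, which lives in [0, sqrt(2)] since
RA vectors sit on the probability simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_io import PairedExpression, ValidationError

__all__ = [
    "UndefinedRAError",
    "ECResult",
    "relative_abundance",
    "liao_zhang_ec",
    "liao_zhang_distance",
]


class UndefinedRAError(ValueError):
    """Relative abundance is undefined for an all-zero profile."""


@dataclass
class ECResult:
    """Per-ortholog conservation scores from one method.

    ``ec`` and ``distance`` are length-k vectors (either may be absent);
    entries where ``valid`` is False are undefined and stored as NaN rather
    than 0, so that invalid pairs never contaminate distribution summaries.
    """

    method: str
    ec: Optional[np.ndarray]
    distance: Optional[np.ndarray]
    valid: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        k = self.valid.shape[0]
        for name in ("ec", "distance"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (k,):
                raise ValidationError(f"{name} vector length does not match valid flags")
            setattr(self, name, v)
        if self.ec is not None:
            defined = self.ec[self.valid & np.isfinite(self.ec)]
            if defined.size and (defined.min() < -1 - 1e-9 or defined.max() > 1 + 1e-9):
                raise ValidationError("defined EC values must lie in [-1, 1]")
        if self.distance is not None:
            defined = self.distance[self.valid & np.isfinite(self.distance)]
            if defined.size and defined.min() < -1e-12:
                raise ValidationError("defined distances must be nonnegative")

    @property
    def k(self) -> int:
        return int(self.valid.shape[0])

    def valid_ec(self) -> np.ndarray:
        """Defined EC values only."""
        if self.ec is None:
            raise ValidationError(f"result {self.method!r} carries no EC vector")
        return self.ec[self.valid & np.isfinite(self.ec)]


def relative_abundance(profile: np.ndarray) -> np.ndarray:
    """Normalize a nonnegative expression profile to relative abundance.

    Returns ``profile / profile.sum()``, a vector on the probability
    simplex; invariant to positive rescaling of the input.
    """
    v = np.asarray(profile, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValidationError("profile must be a vector over at least 3 tissues")
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValidationError("profile must be finite and nonnegative")
    total = v.sum()
    if total <= 0:
        raise UndefinedRAError("relative abundance undefined for an all-zero profile")
    return v / total


def _ra_matrices(paired: PairedExpression) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise RA of both matrices; rows with zero total are NaN-filled."""
    if paired.matrix_A.n_conditions != paired.matrix_B.n_conditions:
        raise ValidationError(
            "corresponding-tissue methods need equal column counts "
            f"({paired.matrix_A.n_conditions} vs {paired.matrix_B.n_conditions})"
        )
    if paired.matrix_A.n_conditions < 3:
        raise ValidationError("need at least 3 corresponding tissues")
    out = []
    defined = np.ones(paired.k, dtype=bool)
    for M in (paired.matrix_A.values, paired.matrix_B.values):
        totals = M.sum(axis=1)
        ok = totals > 0
        ra = np.full_like(M, np.nan, dtype=float)
        ra[ok] = M[ok] / totals[ok, None]
        out.append(ra)
        defined &= ok
    return out[0], out[1], defined


def liao_zhang_ec(paired: PairedExpression) -> ECResult:
    """EC = Pearson correlation of the two RA vectors for each pair.

    Pairs with an undefined RA (all-zero profile) or a constant RA vector
    (zero variance, correlation undefined) are flagged invalid.
    """
    ra_a, ra_b, defined = _ra_matrices(paired)
    k = paired.k
    ec = np.full(k, np.nan)
    valid = defined.copy()
    # constant RA vectors leave Pearson undefined
    with np.errstate(invalid="ignore"):
        valid &= np.nan_to_num(np.ptp(ra_a, axis=1), nan=0.0) > 0
        valid &= np.nan_to_num(np.ptp(ra_b, axis=1), nan=0.0) > 0
    if valid.any():
        xa = ra_a[valid] - ra_a[valid].mean(axis=1, keepdims=True)
        xb = ra_b[valid] - ra_b[valid].mean(axis=1, keepdims=True)
        num = (xa * xb).sum(axis=1)
        den = np.sqrt((xa**2).sum(axis=1) * (xb**2).sum(axis=1))
        ec[valid] = np.clip(num / den, -1.0, 1.0)
    return ECResult(
        method="liao_zhang",
        ec=ec,
        distance=None,
        valid=valid,
        params={"n_common_tissues": paired.matrix_A.n_conditions},
    )


def liao_zhang_distance(paired: PairedExpression) -> ECResult:
    """Euclidean distance between the two RA vectors for each pair.

    Defined whenever both RA vectors exist (constant vectors are fine);
    always in [0, sqrt(2)].
    """
    ra_a, ra_b, defined = _ra_matrices(paired)
    dist = np.full(paired.k, np.nan)
    if defined.any():
        diff = ra_a[defined] - ra_b[defined]
        dist[defined] = np.sqrt((diff**2).sum(axis=1))
    return ECResult(
        method="liao_zhang_distance",
        ec=None,
        distance=dist,
        valid=defined,
        params={"n_common_tissues": paired.matrix_A.n_conditions},
    )
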