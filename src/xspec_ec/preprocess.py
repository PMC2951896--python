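"""Expression filters and tissue subsetting applied before any EC computation.

Filtering is pair-synchronized: dropping ortholog pair i removes row i from
both species' matrices, so every downstream method sees the same k.  The
canonical order is low-expression filtering first, then zero-variance
removal; both are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import PairedExpression, ValidationError

logger = logging.getLogger("xspec_ec")

__all__ = ["FilterReport", "filter_low_expression", "drop_zero_variance", "subset_tissues"]


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step.

    ``n_input_genes`` always equals the retained count plus the removal
    counts (each pair is counted once, by the first rule that removed it).
    ``n_removed_multiprobe`` is recorded for completeness: one-row-per-gene
    input is enforced at read time, so it is zero here.
    """

    n_input_genes: int
    n_removed_low_expression: int = 0
    n_removed_zero_variance: int = 0
    n_removed_multiprobe: int = 0
    retained_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            len(self.retained_ids)
            + self.n_removed_low_expression
            + self.n_removed_zero_variance
            + self.n_removed_multiprobe
        )
        if total != self.n_input_genes:
            raise ValidationError(
                f"filter report does not reconcile: {self.n_input_genes} input vs "
                f"{total} retained+removed"
            )


def filter_low_expression(
    paired: PairedExpression, floor: float = 200.0, mode: str = "max_below"
) -> tuple[PairedExpression, FilterReport]:
    """Remove never-expressed ortholog pairs.

    A pair is dropped when, in either species, the gene's maximum expression
    over all conditions falls below ``floor`` (default 200, the conventional
    MAS 5.0 present-call scale).  Removing genes whose signal never rises
    above the floor limits the influence of low-intensity noise on every
    correlation computed later, while keeping expression vectors complete.
    ``mode="value_mask"`` (masking individual sub-floor values) would create
    incomplete vectors and is rejected.
    """
    if floor < 0:
        raise ValidationError("floor must be nonnegative")
    if mode == "value_mask":
        raise ValidationError(
            "value_mask mode would produce incomplete expression vectors; "
            "only max_below is supported"
        )
    if mode != "max_below":
        raise ValidationError(f"unknown low-expression mode {mode!r}")
    keep = (paired.matrix_A.values.max(axis=1) >= floor) & (
        paired.matrix_B.values.max(axis=1) >= floor
    )
    return _apply_keep(paired, keep, removed_field="n_removed_low_expression")


def drop_zero_variance(paired: PairedExpression) -> tuple[PairedExpression, FilterReport]:
    """Remove pairs whose profile is constant in either species.

    Pearson correlation is undefined for constant vectors; dropping such
    rows up front keeps every later correlation well defined.
    """
    var_ok_a = np.ptp(paired.matrix_A.values, axis=1) > 0
    var_ok_b = np.ptp(paired.matrix_B.values, axis=1) > 0
    keep = var_ok_a & var_ok_b
    return _apply_keep(
        paired, keep, removed_field="n_removed_zero_variance", allow_empty=True
    )


def _apply_keep(
    paired: PairedExpression,
    keep: np.ndarray,
    removed_field: str,
    allow_empty: bool = False,
) -> tuple[PairedExpression, FilterReport]:
    n_removed = int((~keep).sum())
    if n_removed == paired.k and not allow_empty:
        raise ValidationError("all ortholog pairs removed by filter")
    idx = np.flatnonzero(keep)
    out = paired.take_pairs(idx) if n_removed else paired
    report = FilterReport(
        n_input_genes=paired.k,
        retained_ids=[paired.pair_ids[i] for i in idx],
        **{removed_field: n_removed},
    )
    if n_removed:
        logger.info("%s: removed %d of %d pairs", removed_field, n_removed, paired.k)
    return out, report


def subset_tissues(
    paired: PairedExpression, common_A: list[str], common_B: list[str]
) -> PairedExpression:
    """Restrict both species to corresponding tissue panels.

    ``common_A[j]`` and ``common_B[j]`` are the labels of the j-th
    corresponding tissue in each species; the output matrices have exactly
    these columns, in this order, so column j of the A-subset lines up with
    column j of the B-subset.
    """
    if len(common_A) != len(common_B):
        raise ValidationError(
            f"common tissue lists differ in length ({len(common_A)} vs {len(common_B)})"
        )
    if len(common_A) < 3:
        raise ValidationError("need at least 3 corresponding tissues for correlations")
    return PairedExpression(
        paired.matrix_A.take_conditions(common_A),
        paired.matrix_B.take_conditions(common_B),
    )
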