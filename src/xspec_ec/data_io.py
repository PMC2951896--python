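"""Plain-text I/O and the core aligned-expression containers.

Expression tables are tab-delimited, UTF-8: first row holds condition
(tissue) labels, first column holds gene identifiers, every other cell a
nonnegative intensity-scale value.  Ortholog maps are two-column TSV.
EC result tables carry one row per ortholog pair with the method name,
the conservation score and (optionally) the Euclidean divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("xspec_ec")

__all__ = [
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "OrthologMap",
    "PairedExpression",
    "read_expression_table",
    "write_expression_table",
    "read_ortholog_pairs",
    "align_by_orthology",
    "write_ec_table",
    "read_ec_table",
]


class ParseError(ValueError):
    """A cell in an input file could not be interpreted."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Dense gene-by-condition matrix of nonnegative expression intensities.

    Parameters
    ----------
    gene_ids
        Unique row identifiers (genes or probe sets, one per gene).
    condition_labels
        Unique column identifiers (tissues / conditions).
    values
        ``(n_genes, n_conditions)`` array of finite values ``>= 0``.
    """

    gene_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_labels = [str(c) for c in self.condition_labels]
        # C-contiguous so downstream reductions are layout-independent
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.condition_labels)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_labels)} conditions"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicate gene ids: {sorted(dup)}")
        dup = _duplicates(self.condition_labels)
        if dup:
            raise ValidationError(f"duplicate condition labels: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"condition {self.condition_labels[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    def take_genes(self, row_indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(row_indices)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.condition_labels),
            self.values[idx, :],
        )

    def take_conditions(self, labels: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: j for j, c in enumerate(self.condition_labels)}
        cols = []
        for lab in labels:
            if lab not in pos:
                raise ValidationError(f"unknown condition label {lab!r}")
            cols.append(pos[lab])
        return ExpressionMatrix(list(self.gene_ids), list(labels), self.values[:, cols])


@dataclass
class OrthologMap:
    """Ordered 1-1 ortholog pairs ``(gene_id_A, gene_id_B)``."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        dup_a = _duplicates(a for a, _ in self.pairs)
        dup_b = _duplicates(b for _, b in self.pairs)
        if dup_a or dup_b:
            raise ValidationError(
                "orthology is not 1-1; duplicated ids: "
                f"A-side {sorted(dup_a)}, B-side {sorted(dup_b)}"
            )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PairedExpression:
    """Two row-aligned expression matrices; row i is ortholog pair i.

    The two condition panels may differ in size and labels — only the gene
    (row) dimension is aligned across species.
    """

    matrix_A: ExpressionMatrix
    matrix_B: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.matrix_A.n_genes != self.matrix_B.n_genes:
            raise ValidationError(
                "paired matrices must have identical row counts "
                f"({self.matrix_A.n_genes} vs {self.matrix_B.n_genes})"
            )

    @property
    def k(self) -> int:
        """Number of ortholog pairs."""
        return self.matrix_A.n_genes

    @property
    def pair_ids(self) -> list[tuple[str, str]]:
        return list(zip(self.matrix_A.gene_ids, self.matrix_B.gene_ids))

    def take_pairs(self, row_indices: Sequence[int]) -> "PairedExpression":
        return PairedExpression(
            self.matrix_A.take_genes(row_indices),
            self.matrix_B.take_genes(row_indices),
        )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_table(path: str | Path, floor: float | None = None) -> ExpressionMatrix:
    """Read a gene-by-condition TSV into an :class:`ExpressionMatrix`.

    ``floor``, when given, drops genes whose maximum over all conditions is
    below it (a per-matrix convenience; pair-synchronized filtering lives in
    :mod:`xspec_ec.preprocess`).  Empty cells and ``NA`` tokens are rejected:
    downstream correlations require complete vectors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no condition columns found")
    gene_ids = [str(g) for g in df.index]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        # cell-wise float() keeps the text round-trip exact to the ULP
        for i, cell in enumerate(raw):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                v = np.nan
            if not np.isfinite(v):
                raise ParseError(
                    f"{path}: cell at gene {gene_ids[i]!r}, condition {col!r} "
                    f"is not a finite number: {cell!r}"
                )
            values[i, j] = v
    em = ExpressionMatrix(gene_ids, [str(c) for c in df.columns], values)
    if floor is not None:
        keep = np.flatnonzero(em.values.max(axis=1) >= floor)
        em = em.take_genes(keep)
    return em


def write_expression_table(em: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV that round-trips bit-identically through the reader."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(em.condition_labels) + "\n")
        for gid, row in zip(em.gene_ids, em.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_ortholog_pairs(path: str | Path, header: bool = False) -> OrthologMap:
    """Read a two-column TSV of (gene_id_A, gene_id_B) pairs."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and header:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
    return OrthologMap(pairs)


def align_by_orthology(
    A: ExpressionMatrix, B: ExpressionMatrix, omap: OrthologMap
) -> tuple[PairedExpression, int]:
    """Row-align two matrices by a 1-1 ortholog map.

    Pairs whose A-gene is missing from ``A`` or whose B-gene is missing from
    ``B`` are dropped; the retained pairs keep the map's order.  Returns the
    aligned :class:`PairedExpression` and the number of dropped pairs.
    """
    pos_a = {g: i for i, g in enumerate(A.gene_ids)}
    pos_b = {g: i for i, g in enumerate(B.gene_ids)}
    idx_a: list[int] = []
    idx_b: list[int] = []
    dropped = 0
    for ga, gb in omap.pairs:
        ia, ib = pos_a.get(ga), pos_b.get(gb)
        if ia is None or ib is None:
            dropped += 1
            continue
        idx_a.append(ia)
        idx_b.append(ib)
    if not idx_a:
        raise ValidationError("zero retained pairs after orthology alignment")
    if dropped:
        logger.info("align_by_orthology: dropped %d of %d pairs", dropped, len(omap))
    paired = PairedExpression(A.take_genes(idx_a), B.take_genes(idx_b))
    return paired, dropped


# --- EC result tables -------------------------------------------------------

_EC_COLUMNS = ["pair_index", "gene_id_A", "gene_id_B", "method", "ec", "distance", "valid_flag"]


def write_ec_table(result, pair_ids: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write an ECResult as TSV: pair_index, ids, method, ec, distance, valid."""
    k = len(result.valid)
    if len(pair_ids) != k:
        raise ValidationError("pair_ids length does not match result length")
    ec = result.ec if result.ec is not None else np.full(k, np.nan)
    dist = result.distance if result.distance is not None else np.full(k, np.nan)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EC_COLUMNS) + "\n")
        for i in range(k):
            ga, gb = pair_ids[i]
            fh.write(
                f"{i}\t{ga}\t{gb}\t{result.method}\t"
                f"{_fmt(ec[i])}\t{_fmt(dist[i])}\t{int(result.valid[i])}\n"
            )


def read_ec_table(path: str | Path):
    """Read an EC TSV back into an ECResult (plus pair ids)."""
    from .tissue_ec import ECResult  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype={"gene_id_A": str, "gene_id_B": str})
    missing = [c for c in _EC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing EC table columns {missing}")
    methods = df["method"].unique()
    if len(methods) != 1:
        raise ParseError(f"{path}: expected a single method, found {list(methods)}")
    ec = df["ec"].to_numpy(dtype=float)
    dist = df["distance"].to_numpy(dtype=float)
    result = ECResult(
        method=str(methods[0]),
        ec=None if np.all(np.isnan(ec)) else ec,
        distance=None if np.all(np.isnan(dist)) else dist,
        valid=df["valid_flag"].to_numpy(dtype=int).astype(bool),
        params={"source": str(path)},
    )
    pair_ids = list(zip(df["gene_id_A"], df["gene_id_B"]))
    return result, pair_ids


def _fmt(x: float) -> str:
    return "NA" if not np.isfinite(x) else f"{x:.10g}"
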