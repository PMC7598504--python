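"""Downstream arithmetic on a differential-expression table.

The packaged fixture transcribes the published table of genes governing
putrescine abundance in *Salmonella enterica* 14028s grown at 10 mM vs.
0.8 mM Mg2+: per-gene expression in FPKM under both conditions, the printed
log2 fold change, and the FDR-adjusted q-value from the upstream
differential-expression engine (cuffdiff).  q-values are consumed as-is and
never recomputed; ``<0.001`` entries are kept as upper bounds, not point
values.

Fold-change direction is low-Mg over high-Mg, i.e.
``log2(FPKM_0.8mM / FPKM_10mM)`` — the table header does not state the
direction, but multiple rows fix it (e.g. speE, 238 FPKM at 10 mM vs 662 at
0.8 mM, prints +1.47).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateRecordError, InvalidParameterError, ParseError

__all__ = [
    "QBound",
    "ExpressionRecord",
    "packaged_table1_path",
    "read_expression_table",
    "log2_fold_change",
    "flag_differential",
    "summarize_pathways",
    "records_to_frame",
]

DEFAULT_Q_THRESHOLD = 0.05


@dataclass(frozen=True)
class QBound:
    """A q-value that may be an upper bound ("<0.001") rather than a point."""

    value: float
    is_upper_bound: bool

    def __str__(self) -> str:
        return f"<{self.value:g}" if self.is_upper_bound else f"{self.value:g}"


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    pathway: str
    fpkm_high_mg: float  # 10 mM Mg2+ condition
    fpkm_low_mg: float  # 0.8 mM Mg2+ condition
    log2_fc: float  # log2(low / high), full precision
    q_bound: QBound
    differential: bool = False


def packaged_table1_path() -> Path:
    """Filesystem path of the packaged expression-table fixture."""
    return Path(resources.files("topoquant.data") / "table1_expression.tsv")


def _parse_q(cell: str, row_label: str) -> QBound:
    cell = str(cell).strip()
    is_bound = cell.startswith("<")
    raw = cell[1:] if is_bound else cell
    try:
        value = float(raw)
    except ValueError:
        raise ParseError(f"row {row_label!r}: malformed q value {cell!r}") from None
    if not 0 <= value <= 1:
        raise ParseError(f"row {row_label!r}: q value {value} outside [0, 1]")
    return QBound(value, is_bound)


def log2_fold_change(
    fpkm_high_mg: float, fpkm_low_mg: float, pseudocount: float = 0.0
) -> float:
    """log2 fold change of the low-Mg condition over the high-Mg condition.

    Zero FPKM is a hard error unless a positive pseudocount is supplied (no
    row of the packaged table needs one).  Tables report the value rounded to
    2 decimals; full precision is kept internally.
    """
    if pseudocount < 0:
        raise InvalidParameterError("pseudocount must be nonnegative")
    hi = fpkm_high_mg + pseudocount
    lo = fpkm_low_mg + pseudocount
    if hi <= 0 or lo <= 0:
        raise InvalidParameterError(
            "fold change undefined for zero FPKM; supply a positive pseudocount"
        )
    return float(np.log2(lo / hi))


def read_expression_table(path=None) -> list[ExpressionRecord]:
    """Read a TSV of gene, pathway, fpkm_10mM, fpkm_0.8mM, q [, printed_log2fc].

    The fold change is recomputed from the FPKM pair; the printed column, if
    present, is ignored here (tests compare against it separately).  An empty
    file yields an empty list with a warning.
    """
    path = packaged_table1_path() if path is None else path
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        warnings.warn(f"expression table {path} contains no rows", stacklevel=2)
        return []
    required = {"gene", "pathway", "fpkm_10mM", "fpkm_0.8mM", "q"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    records: list[ExpressionRecord] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        gene = str(row["gene"]).strip()
        pathway = str(row["pathway"]).strip()
        if (pathway, gene) in seen:
            raise DuplicateRecordError(f"duplicate gene {gene!r} in pathway {pathway!r}")
        seen.add((pathway, gene))
        try:
            hi = float(row["fpkm_10mM"])
            lo = float(row["fpkm_0.8mM"])
        except ValueError:
            raise ParseError(
                f"row {gene!r}: malformed FPKM value "
                f"({row['fpkm_10mM']!r}, {row['fpkm_0.8mM']!r})"
            ) from None
        if hi < 0 or lo < 0:
            raise ParseError(f"row {gene!r}: negative FPKM")
        records.append(
            ExpressionRecord(
                gene=gene,
                pathway=pathway,
                fpkm_high_mg=hi,
                fpkm_low_mg=lo,
                log2_fc=log2_fold_change(hi, lo),
                q_bound=_parse_q(row["q"], gene),
            )
        )
    return records


def flag_differential(
    records: Iterable[ExpressionRecord], q_threshold: float = DEFAULT_Q_THRESHOLD
) -> list[ExpressionRecord]:
    """Set the differential flag: q (or its upper bound) strictly below the
    threshold.  A q printed as "<0.001" is differential at any usual
    threshold because its bound is below it."""
    if not 0 < q_threshold <= 1:
        raise InvalidParameterError("q_threshold must be in (0, 1]")
    return [
        replace(r, differential=bool(r.q_bound.value < q_threshold)) for r in records
    ]


def summarize_pathways(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Per-pathway direction counts.

    Columns: n_genes, n_differential, n_up_low_mg (log2 fc > 0, higher
    expression at 0.8 mM), n_up_high_mg (log2 fc < 0, higher at 10 mM).
    Pathways appear in first-seen order.
    """
    if not records:
        return pd.DataFrame(
            columns=["pathway", "n_genes", "n_differential", "n_up_low_mg", "n_up_high_mg"]
        )
    rows: dict[str, dict] = {}
    for r in records:
        agg = rows.setdefault(
            r.pathway,
            {"pathway": r.pathway, "n_genes": 0, "n_differential": 0,
             "n_up_low_mg": 0, "n_up_high_mg": 0},
        )
        agg["n_genes"] += 1
        agg["n_differential"] += int(r.differential)
        agg["n_up_low_mg"] += int(r.log2_fc > 0)
        agg["n_up_high_mg"] += int(r.log2_fc < 0)
    return pd.DataFrame(rows.values())


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Tidy frame of records; log2 fold change rounded to 2 decimals for
    display, q rendered with its bound marker."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "pathway": [r.pathway for r in records],
            "fpkm_10mM": [r.fpkm_high_mg for r in records],
            "fpkm_0.8mM": [r.fpkm_low_mg for r in records],
            "log2_fc": [round(r.log2_fc, 2) for r in records],
            "q": [str(r.q_bound) for r in records],
            "differential": [r.differential for r in records],
        }
    )
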