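"""Two-population miRNA expression tables and differential classification.

Expression values are log2-scale array signals, so a fold change between the
two populations is a *difference* of values, not a ratio.  A cell may be
"N.D." (not detected), which is stored as missing — never as zero — and
makes the fold change undefined for that miRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

ND_TOKEN = "N.D."

CLASSES = ("ENRICHED", "DEPLETED", "UNCHANGED", "POP1_ONLY", "POP2_ONLY")


@dataclass
class ExpressionTable:
    """Per-miRNA log2-scale values in two populations.

    ``data`` is indexed by miRNA name with one float column per population;
    missing values (N.D.) are NaN.
    """

    data: pd.DataFrame
    populations: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.populations) != 2:
            raise ValueError("exactly two populations required")
        if list(self.data.columns) != list(self.populations):
            raise ValueError("data columns must match population labels")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate miRNA names: {dups}")
        if len(self.data) and np.isinf(self.data.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError("expression values must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def mirna_names(self) -> list[str]:
        return list(self.data.index)

    def swapped(self) -> "ExpressionTable":
        """The same table with the two populations exchanged."""
        p1, p2 = self.populations
        return ExpressionTable(
            data=self.data[[p2, p1]].copy(), populations=(p2, p1)
        )


def read_expression_table(
    tsv_path: str | Path,
    nd_token: str = ND_TOKEN,
    populations: Optional[tuple[str, str]] = None,
) -> ExpressionTable:
    """Parse a 3-column TSV (miRNA, value_pop1, value_pop2).

    A header row is used for population labels when present; otherwise labels
    default to ``("pop1", "pop2")`` or the ``populations`` argument.  The
    ``nd_token`` cell marks not-detected and is stored as missing.  Duplicate
    miRNA names and non-numeric, non-N.D. cells raise.
    """
    tsv_path = Path(tsv_path)
    if not tsv_path.exists():
        raise FileNotFoundError(tsv_path)
    try:
        raw = pd.read_csv(
            tsv_path, sep="\t", header=None, dtype=str, keep_default_na=False, comment=None
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty:
        labels = populations or ("pop1", "pop2")
        return ExpressionTable(
            data=pd.DataFrame(columns=list(labels), dtype=float), populations=tuple(labels)
        )
    if raw.shape[1] < 3:
        raise ValueError(f"{tsv_path}: expected 3 columns, found {raw.shape[1]}")
    raw = raw.iloc[:, :3]

    def _is_value(cell: str) -> bool:
        if cell == nd_token:
            return True
        try:
            float(cell)
            return True
        except ValueError:
            return False

    first = raw.iloc[0]
    # a header row has no parseable value in either value column
    has_header = not _is_value(first[1]) and not _is_value(first[2])
    if has_header:
        labels = (str(first[1]), str(first[2]))
        raw = raw.iloc[1:]
    else:
        labels = tuple(populations) if populations else ("pop1", "pop2")

    def _parse(cell: str, row: str, col: str) -> float:
        if cell == nd_token:
            return math.nan
        try:
            return float(cell)
        except ValueError:
            raise ValueError(
                f"{tsv_path}: non-numeric, non-{nd_token!r} cell {cell!r} "
                f"(miRNA {row}, column {col})"
            ) from None

    names = raw.iloc[:, 0].tolist()
    values = {
        labels[0]: [_parse(c, n, labels[0]) for n, c in zip(names, raw.iloc[:, 1])],
        labels[1]: [_parse(c, n, labels[1]) for n, c in zip(names, raw.iloc[:, 2])],
    }
    data = pd.DataFrame(values, index=pd.Index(names, name="mirna"))
    return ExpressionTable(data=data, populations=(labels[0], labels[1]))


def log2_fold_change(value_pop1: float, value_pop2: float) -> Optional[float]:
    """log2 fold change pop1 vs pop2: the difference of log2-scale signals.

    Undefined (``None``) when either side is not detected.
    """
    if value_pop1 is None or value_pop2 is None:
        return None
    if math.isnan(value_pop1) or math.isnan(value_pop2):
        return None
    return value_pop1 - value_pop2


@dataclass(frozen=True)
class DifferentialCall:
    mirna_name: str
    log2fc: Optional[float]
    klass: str


def classify_differential(table: ExpressionTable, cutoff: float = 1.0) -> list[DifferentialCall]:
    """Classify each miRNA by fold-change against a symmetric log2 cutoff.

    ENRICHED iff log2fc > cutoff, DEPLETED iff log2fc < -cutoff; a miRNA
    detected in only one population is POP1_ONLY/POP2_ONLY (its fold change
    is undefined but it still belongs to the differential set); miRNAs
    missing in both populations are skipped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    p1, p2 = table.populations
    calls: list[DifferentialCall] = []
    for name, row in table.data.iterrows():
        v1, v2 = float(row[p1]), float(row[p2])
        d1, d2 = not math.isnan(v1), not math.isnan(v2)
        if not d1 and not d2:
            continue
        if d1 and not d2:
            calls.append(DifferentialCall(name, None, "POP1_ONLY"))
            continue
        if d2 and not d1:
            calls.append(DifferentialCall(name, None, "POP2_ONLY"))
            continue
        fc = v1 - v2
        if fc > cutoff:
            klass = "ENRICHED"
        elif fc < -cutoff:
            klass = "DEPLETED"
        else:
            klass = "UNCHANGED"
        calls.append(DifferentialCall(name, fc, klass))
    return calls


def differential_summary(calls: list[DifferentialCall]) -> dict[str, int]:
    """Count calls per class, plus the combined totals used in reporting.

    ``enriched_total`` counts ENRICHED plus POP1_ONLY (detected only in the
    population of interest); ``depleted_total`` symmetrically adds POP2_ONLY.
    """
    counts = {k: 0 for k in CLASSES}
    for c in calls:
        counts[c.klass] += 1
    counts["enriched_total"] = counts["ENRICHED"] + counts["POP1_ONLY"]
    counts["depleted_total"] = counts["DEPLETED"] + counts["POP2_ONLY"]
    return counts


def expressed_mirnas(table: ExpressionTable, population: str) -> set[str]:
    """Names of miRNAs with a detected (non-N.D.) value in one population."""
    if population not in table.populations:
        raise KeyError(
            f"unknown population {population!r}; table has {table.populations}"
        )
    col = table.data[population]
    return set(col.index[col.notna()])


def differential_table(calls: list[DifferentialCall]) -> pd.DataFrame:
    """Differential calls as a DataFrame (mirna, log2fc, class)."""
    return pd.DataFrame(
        [
            {"mirna": c.mirna_name, "log2fc": c.log2fc if c.log2fc is not None else "N/A",
             "class": c.klass}
            for c in calls
        ],
        columns=["mirna", "log2fc", "class"],
    )
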