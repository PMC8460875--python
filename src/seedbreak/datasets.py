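"""Packaged reference tables from the cardiac-NCC miRNA profiling study.

Three small TSVs ship with the package: the 30 most abundant miRNAs in
GFP-positive cardiac neural crest cells (NCCs), the 30 most abundant in
GFP-negative non-NCCs (both with mature sequences and cluster membership),
and the 16-row differential table comparing the two populations (log2-scale
signals, with N.D. for not-detected).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .expression_filter import ExpressionTable
from .seed_sites import MiRNA

DIFFERENTIAL_POPULATIONS = ("cardiac_NCC", "non_NCC")


def _data_path(name: str):
    return resources.files("seedbreak.data").joinpath(name)


def _read_top30(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t")


def cardiac_ncc_top30() -> pd.DataFrame:
    """Top-30 abundance table for cardiac NCCs (mirna, log2_signal, sequence, cluster)."""
    return _read_top30("cardiac_ncc_top30.tsv")


def non_ncc_top30() -> pd.DataFrame:
    """Top-30 abundance table for non-NCCs (mirna, log2_signal, sequence, cluster)."""
    return _read_top30("non_ncc_top30.tsv")


def ncc_differential() -> pd.DataFrame:
    """The differential table verbatim, including the printed log2fc column."""
    with resources.as_file(_data_path("ncc_differential.tsv")) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def ncc_differential_expression() -> ExpressionTable:
    """The differential table as an :class:`ExpressionTable` (N.D. -> missing)."""
    df = ncc_differential()
    data = (
        df.set_index("mirna")[list(DIFFERENTIAL_POPULATIONS)]
        .replace("N.D.", float("nan"))
        .astype(float)
    )
    return ExpressionTable(data=data, populations=DIFFERENTIAL_POPULATIONS)


def profiled_mirnas() -> dict[str, MiRNA]:
    """Mature miRNA sequences from the two top-30 tables, keyed by name."""
    out: dict[str, MiRNA] = {}
    for df in (cardiac_ncc_top30(), non_ncc_top30()):
        for _, row in df.iterrows():
            out.setdefault(row["mirna"], MiRNA(name=row["mirna"], sequence=row["sequence"]))
    return out
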