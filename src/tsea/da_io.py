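"""Ingestion of differential-abundance result tables.

Any DA tool's output can feed the enrichment engine as long as it has a
taxon-name column and a numeric rank column (log2 fold change, effect
size, correlation). Dialect presets cover the column names of three common
tools; ``generic`` requires explicit column names.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import RankedTaxa
from .idmap import normalize_name

logger = logging.getLogger(__name__)

#: Default (taxon_column, rank_column) per dialect. LinDA reports a
#: "log2FoldChange", ALDEx2 reports a standardized "effect", fastANCOM a
#: log fold change ("logFC").
DIALECT_PRESETS: dict[str, tuple[str, str]] = {
    "linda": ("taxon", "log2FoldChange"),
    "aldex2": ("taxon", "effect"),
    "fastancom": ("taxon", "logFC"),
}


@dataclass(frozen=True)
class DaTableSpec:
    """How to interpret a DA output table.

    ``dialect`` presets fill in default column names; explicit
    ``taxon_column`` / ``rank_column`` always win. ``delimiter`` of None
    means: infer from the file suffix (.csv -> comma, otherwise tab).
    """

    taxon_column: str | None = None
    rank_column: str | None = None
    delimiter: str | None = None
    dialect: str = "generic"

    def resolved(self) -> "DaTableSpec":
        taxon, rank = self.taxon_column, self.rank_column
        if self.dialect != "generic":
            if self.dialect not in DIALECT_PRESETS:
                raise ValueError(
                    f"unknown dialect {self.dialect!r}; expected one of "
                    f"{('generic', *DIALECT_PRESETS)}"
                )
            preset_taxon, preset_rank = DIALECT_PRESETS[self.dialect]
            taxon = taxon or preset_taxon
            rank = rank or preset_rank
        if taxon is None or rank is None:
            raise ValueError(
                "generic tables need explicit taxon_column and rank_column"
            )
        return replace(self, taxon_column=taxon, rank_column=rank)


def ranked_from_frame(
    frame: pd.DataFrame, taxon_col: str, rank_col: str
) -> RankedTaxa:
    """Build :class:`RankedTaxa` from a DataFrame of DA results.

    Taxon names are normalised; rows with missing or non-finite rank
    values are dropped with a logged count; duplicate taxa are an error
    (ambiguous input), as is an empty table after dropping.
    """
    for col in (taxon_col, rank_col):
        if col not in frame.columns:
            raise ValueError(
                f"column {col!r} not found; available columns: "
                f"{list(frame.columns)}"
            )
    taxa = frame[taxon_col].astype(str).map(normalize_name)
    values = pd.to_numeric(frame[rank_col], errors="coerce")
    keep = np.isfinite(values.to_numpy(dtype=float))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with missing/non-finite rank values",
                       n_dropped)
    taxa, values = taxa[keep], values[keep]
    dupes = taxa[taxa.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate taxon in input table: {dupes[:5]}")
    if len(taxa) == 0:
        raise ValueError("no usable rows: every rank value was missing")
    return RankedTaxa(zip(taxa, values.astype(float)))


def read_da_table(path: str | Path, spec: DaTableSpec) -> RankedTaxa:
    """Read a DA results table (TSV/CSV) into a ranked taxon list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    spec = spec.resolved()
    sep = spec.delimiter or ("," if path.suffix.lower() == ".csv" else "\t")
    frame = pd.read_csv(path, sep=sep)
    return ranked_from_frame(frame, spec.taxon_column, spec.rank_column)


def write_da_table(
    ranked: RankedTaxa,
    path: str | Path,
    taxon_col: str = "taxon",
    rank_col: str = "log2FoldChange",
) -> None:
    """Write a ranked taxon list back out as a generic TSV table."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([taxon_col, rank_col])
        for taxon, value in ranked.items():
            writer.writerow([taxon, format(value, ".10g")])
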