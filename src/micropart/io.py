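"""Reading and writing count tables and metadata as UTF-8 TSV.

Count tables follow a BIOM-TSV-like dialect: the header's first cell is
``#OTU_ID``, one column per sample, and an optional final ``taxonomy``
column.  Default orientation is OTUs as rows (amplicon convention); a flag
accepts the transposed layout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata

logger = logging.getLogger(__name__)

OTU_ID_HEADER = "#OTU_ID"
TAXONOMY_COLUMN = "taxonomy"

__all__ = ["read_count_table", "write_count_table", "read_metadata", "align_samples"]


def read_count_table(path: str | Path, orientation: str = "otus_as_rows") -> CountTable:
    """Read a tab-separated count table.

    Parameters
    ----------
    path
        TSV file whose first header cell is the row-id label (``#OTU_ID``),
        with an optional trailing ``taxonomy`` column.
    orientation
        ``"otus_as_rows"`` (default) or ``"samples_as_rows"``.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: empty table")
    id_col = df.columns[0]
    row_ids = df[id_col].astype(str).tolist()
    taxonomy = None
    body = df.drop(columns=[id_col])
    if TAXONOMY_COLUMN in body.columns:
        tax_series = body.pop(TAXONOMY_COLUMN)
        taxonomy = dict(zip(row_ids, tax_series.astype(str)))
    col_ids = [str(c) for c in body.columns]
    values = np.empty((len(row_ids), len(col_ids)), dtype=np.int64)
    for j, col in enumerate(body.columns):
        raw = body[col]
        num = pd.to_numeric(raw, errors="coerce")
        if num.isna().any():
            i = int(num.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value {raw.iloc[i]!r} at row {row_ids[i]!r}, "
                f"column {col_ids[j]!r}"
            )
        arr = num.to_numpy(dtype=float)
        if (arr != np.floor(arr)).any():
            i = int(np.argmax(arr != np.floor(arr)))
            raise ValueError(
                f"{path}: non-integer count {arr[i]!r} at row {row_ids[i]!r}, "
                f"column {col_ids[j]!r}"
            )
        if (arr < 0).any():
            i = int(np.argmax(arr < 0))
            raise ValueError(
                f"{path}: negative count {int(arr[i])} at row {row_ids[i]!r}, "
                f"column {col_ids[j]!r}"
            )
        values[:, j] = arr.astype(np.int64)
    if orientation == "samples_as_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
        if taxonomy is not None:
            raise ValueError("taxonomy column is only supported with OTUs as rows")
    return CountTable(row_ids, col_ids, values, taxonomy)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as TSV with deterministic row/column order."""
    df = table.to_dataframe()
    if table.taxonomy is not None:
        df[TAXONOMY_COLUMN] = [table.taxonomy.get(o, "") for o in table.otu_ids]
    df.index.name = OTU_ID_HEADER
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path: str | Path, day_span: float | None = None) -> SampleMetadata:
    """Read sample metadata from TSV.

    Requires ``sample_id``, ``sex`` and ``cage``.  The phenotype comes from an
    ``adg`` column (g/day) when present; otherwise it is derived as
    ``(finishing_weight - weaning_weight) * 1000 / days`` with weights in kg.
    The day span is taken from a ``days`` column, or from ``day_span``.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    for col in ("sample_id", "sex", "cage"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata missing required column {col!r}")
    if "adg" not in df.columns:
        for col in ("weaning_weight", "finishing_weight"):
            if col not in df.columns:
                raise ValueError(
                    f"{path}: metadata needs an 'adg' column or both weight columns; "
                    f"missing {col!r}"
                )
        if "days" in df.columns:
            days = pd.to_numeric(df["days"]).to_numpy(dtype=float)
        elif day_span is not None:
            days = float(day_span)
        else:
            raise ValueError(f"{path}: deriving adg from weights requires 'days' or day_span")
        gain_kg = pd.to_numeric(df["finishing_weight"]) - pd.to_numeric(df["weaning_weight"])
        df["adg"] = gain_kg.to_numpy(dtype=float) * 1000.0 / days
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def align_samples(table: CountTable, metadata: SampleMetadata) -> tuple[CountTable, SampleMetadata]:
    """Restrict both inputs to their common samples, in the table's order."""
    meta_ids = set(metadata.sample_ids)
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise ValueError("no samples shared between count table and metadata")
    dropped_t = [s for s in table.sample_ids if s not in meta_ids]
    dropped_m = [s for s in metadata.sample_ids if s not in set(table.sample_ids)]
    if dropped_t:
        logger.info("align_samples: dropping %d table samples without metadata: %s",
                    len(dropped_t), dropped_t)
    if dropped_m:
        logger.info("align_samples: dropping %d metadata samples without counts: %s",
                    len(dropped_m), dropped_m)
    return table.select_samples(shared), metadata.select_samples(shared)
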