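"""Readers, writers and the data model for plate maps, raw readouts and
result tables.

All interchange files are plain CSV (UTF-8, comma separator, ``.`` decimal,
header required). Wells are named row-letter + zero-padded two-digit column
("A01"); internal coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import pandas as pd

from arrayscreen.errors import SchemaError

CONTENT_TYPES = frozenset(
    {"mock", "blank", "scrambled", "positive_control", "gene"}
)

#: plate format -> (n_rows, n_cols)
PLATE_FORMATS = {96: (8, 12), 384: (16, 24)}

PLATE_MAP_COLUMNS = [
    "plate_id", "well", "content_type", "gene_symbol", "guide_id", "replicate",
]
READOUT_COLUMNS = ["plate_id", "well", "raw_luminescence"]
RESULT_COLUMNS = [
    "cell_line", "gene_symbol", "guide_id", "n_replicates",
    "mean_normalized_viability", "lod", "hit",
]


@dataclass(frozen=True)
class WellRecord:
    """Annotation of a single well: where it is and what it contains."""

    plate_id: str
    well: str
    row: int
    col: int
    content_type: str
    gene_symbol: str = ""
    guide_id: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.content_type not in CONTENT_TYPES:
            raise SchemaError(
                f"unknown content_type {self.content_type!r} in well "
                f"{self.plate_id}/{self.well}"
            )
        if self.content_type == "gene" and not self.gene_symbol:
            raise SchemaError(
                f"gene well {self.plate_id}/{self.well} lacks a gene_symbol"
            )
        if self.content_type in ("mock", "blank") and (
            self.gene_symbol or self.guide_id
        ):
            raise SchemaError(
                f"{self.content_type} well {self.plate_id}/{self.well} must "
                "have empty gene_symbol and guide_id"
            )
        if (self.row, self.col) != well_to_rowcol(self.well):
            raise SchemaError(
                f"well name {self.well!r} does not match coordinates "
                f"({self.row}, {self.col})"
            )
        if self.replicate < 1:
            raise SchemaError("replicate must be a positive integer")


def well_to_rowcol(well: str) -> tuple[int, int]:
    """Map a well name like ``"A01"`` to 0-based ``(row, col)``.

    ``"H12"`` -> ``(7, 11)``.
    """
    if len(well) < 2 or well[0] not in string.ascii_uppercase:
        raise SchemaError(f"malformed well name {well!r}")
    row = string.ascii_uppercase.index(well[0])
    try:
        col = int(well[1:]) - 1
    except ValueError as exc:
        raise SchemaError(f"malformed well name {well!r}") from exc
    if col < 0:
        raise SchemaError(f"malformed well name {well!r}")
    return row, col


def rowcol_to_well(row: int, col: int) -> str:
    """Map 0-based ``(row, col)`` to a well name; inverse of
    :func:`well_to_rowcol`."""
    if not (0 <= row < 26) or col < 0:
        raise SchemaError(f"coordinates ({row}, {col}) outside the plate")
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_plate_map(path) -> list[WellRecord]:
    """Read a plate-map CSV into :class:`WellRecord` objects.

    Schema: ``plate_id,well,content_type,gene_symbol,guide_id,replicate``.
    Duplicate ``(plate_id, well)`` pairs and unknown content types raise
    :class:`~arrayscreen.errors.SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, PLATE_MAP_COLUMNS, path)
    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise SchemaError(
            f"{path}: duplicate well {first['plate_id']}/{first['well']}"
        )
    records = []
    for tup in df.itertuples(index=False):
        row, col = well_to_rowcol(tup.well)
        records.append(
            WellRecord(
                plate_id=tup.plate_id,
                well=tup.well,
                row=row,
                col=col,
                content_type=tup.content_type,
                gene_symbol=tup.gene_symbol,
                guide_id=tup.guide_id,
                replicate=int(tup.replicate) if tup.replicate else 1,
            )
        )
    return records


def plate_map_frame(records: list[WellRecord]) -> pd.DataFrame:
    """Tabular view of a plate map, one row per well."""
    return pd.DataFrame(
        [
            {
                "plate_id": r.plate_id,
                "well": r.well,
                "row": r.row,
                "col": r.col,
                "content_type": r.content_type,
                "gene_symbol": r.gene_symbol,
                "guide_id": r.guide_id,
                "replicate": r.replicate,
            }
            for r in records
        ]
    )


def write_plate_map(records: list[WellRecord], path) -> None:
    df = plate_map_frame(records)[PLATE_MAP_COLUMNS]
    df.to_csv(path, index=False)


def read_readouts(path) -> pd.DataFrame:
    """Read a raw-luminescence CSV (``plate_id,well,raw_luminescence``).

    Values must be non-negative and unique per ``(plate_id, well)``.
    """
    df = pd.read_csv(
        path, dtype={"plate_id": str, "well": str, "raw_luminescence": float}
    )
    _require_columns(df, READOUT_COLUMNS, path)
    if df["raw_luminescence"].isna().any():
        raise SchemaError(f"{path}: non-numeric or missing luminescence value")
    if (df["raw_luminescence"] < 0).any():
        bad = df.loc[df["raw_luminescence"] < 0].iloc[0]
        raise SchemaError(
            f"{path}: negative luminescence {bad['raw_luminescence']} in "
            f"{bad['plate_id']}/{bad['well']}"
        )
    if df.duplicated(subset=["plate_id", "well"]).any():
        raise SchemaError(f"{path}: duplicate (plate_id, well) in readouts")
    return df[READOUT_COLUMNS].copy()


def write_readouts(df: pd.DataFrame, path) -> None:
    df[READOUT_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def write_result_table(results: pd.DataFrame, path) -> None:
    """Write a hit-calling result table; round-trips losslessly to 12
    significant digits."""
    _require_columns(results, RESULT_COLUMNS, "<result table>")
    results[RESULT_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_result_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, RESULT_COLUMNS, path)
    df = df[RESULT_COLUMNS].copy()
    df["n_replicates"] = df["n_replicates"].astype(int)
    df["mean_normalized_viability"] = df["mean_normalized_viability"].astype(
        float
    )
    df["lod"] = df["lod"].astype(float)
    bad = ~df["hit"].isin(["True", "False"])
    if bad.any():
        raise SchemaError(f"{path}: hit column must be True/False")
    df["hit"] = df["hit"] == "True"
    return df
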