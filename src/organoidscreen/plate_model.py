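"""Domain types and I/O for the screen's well-level data.

The atom of a screen is one assay measurement of one well, carrying its
plate position, control role, treatment annotation and dose. A screen is
held as a long-format :class:`pandas.DataFrame` wrapped in
:class:`ScreenDataset`; spatial operations view one plate x assay as a
:class:`PlateGrid` matrix (rows x columns, NaN for masked wells).

The interchange format is a long-format CSV with one row per
(well, assay) measurement; row coordinates are letters (A=1) in the file
and 1-based integers in memory.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AssayKind",
    "ControlRole",
    "WellAddress",
    "WellRecord",
    "PlateGrid",
    "ScreenDataset",
    "SchemaError",
    "IntegrityError",
    "read_well_table",
    "write_well_table",
    "pivot_to_grid",
    "WELL_TABLE_COLUMNS",
    "row_label",
    "row_index",
]

#: Canonical CSV header, in order.
WELL_TABLE_COLUMNS = [
    "screen_id",
    "donor",
    "plate",
    "well_row",
    "well_col",
    "role",
    "treatment_id",
    "target_annotation",
    "dose_uM",
    "assay",
    "raw_value",
]

_ROW_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class IntegrityError(ValueError):
    """A table violates a uniqueness or consistency invariant."""


class AssayKind(str, enum.Enum):
    """The three multiplexed readouts of the screen.

    ATP is the CellTiter-Glo viability/cell-number readout; LYZ.NS and
    LYZ.S are the basal (non-stimulated) and carbachol-stimulated
    lysozyme-secretion readouts.
    """

    ATP = "ATP"
    LYZ_NS = "LYZ.NS"
    LYZ_S = "LYZ.S"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ControlRole(str, enum.Enum):
    """Role of a well: compound, one of four vehicle roles, or no-cell.

    Vehicle (DMSO) wells are labelled A-D by stimulation order across
    the two lysozyme assay phases; NO_CELL wells contain assay reagents
    but no organoids and read at background.
    """

    COMPOUND = "COMPOUND"
    VEHICLE_A = "VEHICLE_A"
    VEHICLE_B = "VEHICLE_B"
    VEHICLE_C = "VEHICLE_C"
    VEHICLE_D = "VEHICLE_D"
    NO_CELL = "NO_CELL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The four vehicle roles, in stimulation-order label order.
VEHICLE_ROLES = (
    ControlRole.VEHICLE_A,
    ControlRole.VEHICLE_B,
    ControlRole.VEHICLE_C,
    ControlRole.VEHICLE_D,
)


def row_label(row: int) -> str:
    """1-based row index -> plate letter (1 -> 'A')."""
    if not 1 <= row <= 26:
        raise ValueError(f"row index {row} outside A-Z range")
    return _ROW_LETTERS[row - 1]


def row_index(label: str) -> int:
    """Plate letter -> 1-based row index ('A' -> 1). Integers pass through."""
    s = str(label).strip()
    if s.isdigit():
        return int(s)
    s = s.upper()
    if len(s) != 1 or s not in _ROW_LETTERS:
        raise SchemaError(f"unrecognised well row label {label!r}")
    return _ROW_LETTERS.index(s) + 1


@dataclass(frozen=True)
class WellAddress:
    """Position of one well: plate identifier plus 1-based row/column."""

    plate_id: str
    row: int
    col: int

    def label(self) -> str:
        return f"{self.plate_id}:{row_label(self.row)}{self.col:02d}"


@dataclass(frozen=True)
class WellRecord:
    """One assay measurement of one well with its metadata."""

    address: WellAddress
    donor: str
    role: ControlRole
    assay: AssayKind
    raw_value: float
    treatment_id: str = ""
    target_annotation: str = ""
    dose_uM: float | None = None
    screen_id: str = ""

    def __post_init__(self) -> None:
        if not self.raw_value > 0:
            raise ValueError(
                f"raw_value must be positive (log10 undefined) at well "
                f"{self.address.label()} [{self.assay}]: {self.raw_value!r}"
            )
        has_treat = bool(self.treatment_id) and self.dose_uM is not None
        if (self.role is ControlRole.COMPOUND) != has_treat:
            raise ValueError(
                f"role {self.role} inconsistent with treatment_id/dose at "
                f"{self.address.label()}: compound wells and only compound "
                "wells carry a treatment and dose"
            )


@dataclass
class PlateGrid:
    """One plate x assay as a rows x cols matrix; NaN marks masked wells."""

    plate_id: str
    assay: AssayKind
    values: np.ndarray  # float matrix, shape (rows, cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class ScreenDataset:
    """A validated long-format screen table.

    ``frame`` holds one row per (plate, well, assay) measurement with the
    canonical columns (integer 1-based ``well_row``/``well_col``).
    ``provenance`` echoes how the data were produced (config + seed when
    synthetic).
    """

    frame: pd.DataFrame
    geometry: tuple[int, int] = (16, 24)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame, self.geometry)

    # -- convenience -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def plates(self) -> list[str]:
        return sorted(self.frame["plate"].unique())

    @property
    def assays(self) -> list[str]:
        return sorted(self.frame["assay"].unique())

    def records(self) -> Iterable[WellRecord]:
        """Yield rows as :class:`WellRecord` objects."""
        for t in self.frame.itertuples(index=False):
            dose = None if pd.isna(t.dose_uM) else float(t.dose_uM)
            yield WellRecord(
                address=WellAddress(str(t.plate), int(t.well_row), int(t.well_col)),
                donor=str(t.donor),
                role=ControlRole(t.role),
                assay=AssayKind(t.assay),
                raw_value=float(t.raw_value),
                treatment_id="" if pd.isna(t.treatment_id) else str(t.treatment_id),
                target_annotation=""
                if pd.isna(t.target_annotation)
                else str(t.target_annotation),
                dose_uM=dose,
                screen_id="" if pd.isna(t.screen_id) else str(t.screen_id),
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[WellRecord],
        geometry: tuple[int, int] = (16, 24),
        provenance: Mapping | None = None,
    ) -> "ScreenDataset":
        rows = [
            {
                "screen_id": r.screen_id,
                "donor": r.donor,
                "plate": r.address.plate_id,
                "well_row": r.address.row,
                "well_col": r.address.col,
                "role": r.role.value,
                "treatment_id": r.treatment_id,
                "target_annotation": r.target_annotation,
                "dose_uM": np.nan if r.dose_uM is None else r.dose_uM,
                "assay": r.assay.value,
                "raw_value": r.raw_value,
            }
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=WELL_TABLE_COLUMNS)
        return cls(frame, geometry=geometry, provenance=dict(provenance or {}))


def _validate_frame(frame: pd.DataFrame, geometry: tuple[int, int]) -> pd.DataFrame:
    missing = [c for c in WELL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"well table missing required columns: {missing}")
    frame = frame[WELL_TABLE_COLUMNS].copy()

    frame["well_row"] = frame["well_row"].map(row_index)
    frame["well_col"] = frame["well_col"].astype(int)
    frame["plate"] = frame["plate"].astype(str)
    frame["donor"] = frame["donor"].astype(str)
    frame["raw_value"] = frame["raw_value"].astype(float)
    frame["dose_uM"] = pd.to_numeric(frame["dose_uM"], errors="coerce")

    n_rows, n_cols = geometry
    bad_geom = (
        (frame["well_row"] < 1)
        | (frame["well_row"] > n_rows)
        | (frame["well_col"] < 1)
        | (frame["well_col"] > n_cols)
    )
    if bad_geom.any():
        first = frame[bad_geom].iloc[0]
        raise IntegrityError(
            f"well ({first['plate']}, row {first['well_row']}, col "
            f"{first['well_col']}) outside {n_rows}x{n_cols} geometry"
        )

    valid_roles = {r.value for r in ControlRole}
    bad_role = ~frame["role"].isin(valid_roles)
    if bad_role.any():
        raise SchemaError(
            f"unknown role value(s): {sorted(frame.loc[bad_role, 'role'].unique())}"
        )
    valid_assays = {a.value for a in AssayKind}
    bad_assay = ~frame["assay"].isin(valid_assays)
    if bad_assay.any():
        raise SchemaError(
            f"unknown assay value(s): {sorted(frame.loc[bad_assay, 'assay'].unique())}"
        )

    nonpos = ~(frame["raw_value"] > 0)
    if nonpos.any():
        first = frame[nonpos].iloc[0]
        raise ValueError(
            "non-positive raw_value (log10 undefined) at well "
            f"{first['plate']}:{row_label(int(first['well_row']))}"
            f"{int(first['well_col']):02d} [{first['assay']}]: "
            f"{first['raw_value']!r}"
        )

    dup = frame.duplicated(subset=["plate", "well_row", "well_col", "assay"])
    if dup.any():
        first = frame[dup].iloc[0]
        raise IntegrityError(
            "duplicate (plate, well, assay) measurement at "
            f"{first['plate']}:{row_label(int(first['well_row']))}"
            f"{int(first['well_col']):02d} [{first['assay']}]"
        )

    is_comp = frame["role"] == ControlRole.COMPOUND.value
    has_treat = frame["treatment_id"].fillna("").astype(str).str.len().gt(0) & frame[
        "dose_uM"
    ].notna()
    inconsistent = is_comp != has_treat
    if inconsistent.any():
        first = frame[inconsistent].iloc[0]
        raise IntegrityError(
            f"role/treatment inconsistency at {first['plate']}:"
            f"{row_label(int(first['well_row']))}{int(first['well_col']):02d}: "
            "compound wells and only compound wells carry treatment_id and dose"
        )

    frame["treatment_id"] = frame["treatment_id"].fillna("").astype(str)
    frame["target_annotation"] = frame["target_annotation"].fillna("").astype(str)
    frame["screen_id"] = frame["screen_id"].fillna("").astype(str)
    return frame.reset_index(drop=True)


def read_well_table(
    path: str | Path, geometry: tuple[int, int] = (16, 24)
) -> ScreenDataset:
    """Read and validate a long-format well table CSV.

    Row letters A-P are mapped to 1-based integers. Raises
    :class:`SchemaError` for missing columns, :class:`IntegrityError` for
    duplicate (plate, well, assay) triples, and :class:`ValueError` for
    non-positive raw values (the error names the offending well).
    """
    frame = pd.read_csv(path, dtype={"plate": str, "donor": str, "well_row": str})
    return ScreenDataset(frame, geometry=geometry)


def write_well_table(dataset: ScreenDataset, path: str | Path) -> Path:
    """Write a dataset as the canonical CSV (rows as letters, sorted by
    plate, row, col, assay). Round-trips exactly through
    :func:`read_well_table`."""
    out = dataset.frame.sort_values(
        ["plate", "well_row", "well_col", "assay"], kind="mergesort"
    ).copy()
    out["well_row"] = out["well_row"].map(row_label)
    path = Path(path)
    out.to_csv(path, index=False, columns=WELL_TABLE_COLUMNS)
    return path


def pivot_to_grid(
    dataset: ScreenDataset,
    plate_id: str,
    assay: AssayKind | str,
    mask_roles: Iterable[ControlRole | str] = (),
    column: str = "raw_value",
) -> PlateGrid:
    """View one plate x assay as a matrix, with masked roles set to NaN.

    ``column`` selects which value column to pivot (e.g. ``raw_value`` or
    a previously added ``log10_value``). Wells absent from the table are
    NaN; wells whose role is in ``mask_roles`` are NaN as well.
    """
    assay = AssayKind(assay).value
    mask_values = {ControlRole(r).value for r in mask_roles}
    sub = dataset.frame[
        (dataset.frame["plate"] == str(plate_id)) & (dataset.frame["assay"] == assay)
    ]
    if sub.empty:
        raise KeyError(f"no wells for plate {plate_id!r}, assay {assay!r}")
    if column not in sub.columns:
        raise KeyError(f"column {column!r} not present in dataset")
    n_rows, n_cols = dataset.geometry
    values = np.full((n_rows, n_cols), np.nan)
    keep = ~sub["role"].isin(mask_values)
    kept = sub[keep]
    values[kept["well_row"].to_numpy() - 1, kept["well_col"].to_numpy() - 1] = kept[
        column
    ].to_numpy(dtype=float)
    return PlateGrid(plate_id=str(plate_id), assay=AssayKind(assay), values=values)
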