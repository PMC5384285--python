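"""Typed readers and writers for the screen's tabular inputs, plus packaged
reference fixtures.

Three CSV schemas are supported (comma-separated, UTF-8, ``.`` decimal,
header mandatory):

* ``compounds(compound_id,name,category,smiles,source)``
* ``plate(plate_id,well,compound_id,role,concentration_um,absorbance,replicate)``
* ``ct(sample_id,condition,gene_role,gene_name,ct,experiment_id)``

The packaged fixtures (``table1``, ``table2``, ``table3``) are transcriptions
of the published confirmation list, the raw multi-assay score table and the
mixed-glia significance table, stored at the printed precision.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "CompoundRecord",
    "PlateWell",
    "CtMeasurement",
    "PaperFixture",
    "WellRole",
    "Condition",
    "GeneRole",
    "read_compound_table",
    "write_compound_table",
    "read_plate_table",
    "write_plate_table",
    "read_ct_table",
    "write_ct_table",
    "load_paper_fixture",
    "fixture_checksum",
    "normalize_compound_name",
]


class WellRole(str, Enum):
    DRUG = "drug"
    VEHICLE = "vehicle"
    POS_CONTROL_PROLIF = "pos_control_prolif"
    POS_CONTROL_DIFF = "pos_control_diff"
    BLANK = "blank"


class Condition(str, Enum):
    TREATED = "treated"
    CONTROL = "control"


class GeneRole(str, Enum):
    TARGET = "target"
    REFERENCE = "reference"


@dataclass(frozen=True)
class CompoundRecord:
    """Identity of one library compound."""

    compound_id: str
    name: str
    category: str = ""
    smiles: Optional[str] = None
    source: str = "library"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("compound name must be non-empty")


@dataclass(frozen=True)
class PlateWell:
    """One absorbance measurement from the colorimetric viability plate."""

    plate_id: str
    well: str
    role: WellRole
    absorbance: float
    compound_id: Optional[str] = None
    concentration_um: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role is WellRole.DRUG and not self.compound_id:
            raise ValidationError(
                f"well {self.plate_id}/{self.well}: role=drug requires compound_id"
            )
        if not np.isfinite(self.absorbance) or self.absorbance < 0:
            raise ValidationError(
                f"well {self.plate_id}/{self.well}: absorbance must be finite and >= 0, "
                f"got {self.absorbance}"
            )
        if self.concentration_um < 0:
            raise ValidationError("concentration_um must be >= 0")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR cycle-threshold measurement."""

    sample_id: str
    condition: Condition
    gene_role: GeneRole
    gene_name: str
    ct: float
    experiment_id: str = "E1"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValidationError(
                f"sample {self.sample_id}, gene {self.gene_name}: ct must be finite "
                f"and > 0, got {self.ct}"
            )


@dataclass(frozen=True)
class PaperFixture:
    """A packaged transcription of one published table."""

    name: str
    rows: pd.DataFrame = field(repr=False)


_FIXTURE_NAMES = ("table1", "table2", "table3")

# Known cross-table spelling variants of the same compound.
_NAME_ALIASES = {
    "METHOXYISOFLAVONE": "5-METHYL-7-METHOXYISOFLAVONE",
}


def normalize_compound_name(name: str) -> str:
    """Canonicalize a compound name for cross-table matching.

    Uppercases, collapses whitespace, strips parenthetical suffixes such as
    ``(2X)`` or ``(OR-486)`` and resolves known printed abbreviations.
    """
    s = re.sub(r"\s*\([^)]*\)\s*$", "", name.strip().upper())
    s = re.sub(r"\s+", " ", s)
    return _NAME_ALIASES.get(s, s)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file has no header row") from exc


def _to_float(value: str, path, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(
            f"{path}: row {row}: column '{column}' value {value!r} is not numeric"
        ) from exc


def read_compound_table(path) -> list[CompoundRecord]:
    """Read a compound-library CSV into validated records.

    Raises :class:`SchemaError` on a missing column and
    :class:`ValidationError` on a duplicated ``compound_id``.
    """
    df = _read_csv(path)
    _require_columns(df, ["compound_id", "name"], path)
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        cid = row["compound_id"]
        if cid in seen:
            raise ValidationError(f"{path}: duplicate compound_id '{cid}'")
        seen.add(cid)
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=row["name"],
                category=row.get("category", ""),
                smiles=row.get("smiles") or None,
                source=row.get("source", "library") or "library",
            )
        )
    return records


def write_compound_table(records: Iterable[CompoundRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "category": r.category,
                "smiles": r.smiles or "",
                "source": r.source,
            }
            for r in records
        ],
        columns=["compound_id", "name", "category", "smiles", "source"],
    ).to_csv(path, index=False)


def read_plate_table(path) -> list[PlateWell]:
    """Read a plate-absorbance CSV; well roles are normalized case-insensitively."""
    df = _read_csv(path)
    _require_columns(df, ["plate_id", "well", "role", "absorbance"], path)
    wells: list[PlateWell] = []
    for i, row in df.iterrows():
        role_raw = row["role"].strip().lower()
        try:
            role = WellRole(role_raw)
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: unknown well role {row['role']!r}") from exc
        wells.append(
            PlateWell(
                plate_id=row["plate_id"],
                well=row["well"],
                role=role,
                absorbance=_to_float(row["absorbance"], path, i + 2, "absorbance"),
                compound_id=row.get("compound_id") or None,
                concentration_um=_to_float(row["concentration_um"], path, i + 2, "concentration_um")
                if row.get("concentration_um")
                else 0.0,
                replicate=int(row["replicate"]) if row.get("replicate") else 1,
            )
        )
    return wells


def write_plate_table(wells: Iterable[PlateWell], path) -> None:
    pd.DataFrame(
        [
            {
                "plate_id": w.plate_id,
                "well": w.well,
                "compound_id": w.compound_id or "",
                "role": w.role.value,
                "concentration_um": w.concentration_um,
                "absorbance": w.absorbance,
                "replicate": w.replicate,
            }
            for w in wells
        ],
        columns=[
            "plate_id",
            "well",
            "compound_id",
            "role",
            "concentration_um",
            "absorbance",
            "replicate",
        ],
    ).to_csv(path, index=False)


def read_ct_table(path) -> list[CtMeasurement]:
    """Read a qPCR Ct CSV.

    Target/reference pairing is *not* checked here; it is validated lazily at
    the ddCt computation site, so partially collected experiments still load.
    """
    df = _read_csv(path)
    _require_columns(df, ["sample_id", "condition", "gene_role", "gene_name", "ct"], path)
    out: list[CtMeasurement] = []
    for i, row in df.iterrows():
        try:
            condition = Condition(row["condition"].strip().lower())
            gene_role = GeneRole(row["gene_role"].strip().lower())
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: bad condition/gene_role") from exc
        out.append(
            CtMeasurement(
                sample_id=row["sample_id"],
                condition=condition,
                gene_role=gene_role,
                gene_name=row["gene_name"],
                ct=_to_float(row["ct"], path, i + 2, "ct"),
                experiment_id=row.get("experiment_id") or "E1",
            )
        )
    return out


def write_ct_table(measurements: Iterable[CtMeasurement], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "condition": m.condition.value,
                "gene_role": m.gene_role.value,
                "gene_name": m.gene_name,
                "ct": m.ct,
                "experiment_id": m.experiment_id,
            }
            for m in measurements
        ],
        columns=["sample_id", "condition", "gene_role", "gene_name", "ct", "experiment_id"],
    ).to_csv(path, index=False)


def _fixture_path(name: str):
    return resources.files("restage.fixtures").joinpath(f"{name}.csv")


def load_paper_fixture(name: str) -> PaperFixture:
    """Load a packaged table transcription by name (``table1``..``table3``).

    The shipped values are validated against the structural invariants of the
    published tables (row counts per role).
    """
    if name not in _FIXTURE_NAMES:
        raise KeyError(f"unknown fixture '{name}'; expected one of {_FIXTURE_NAMES}")
    with resources.as_file(_fixture_path(name)) as p:
        df = pd.read_csv(p)
    if name == "table1" and len(df) != 43:
        raise ValidationError("table1 fixture must have 43 rows (42 hits + internal control)")
    if name == "table2":
        n_compound = int((df["role"] == "compound").sum())
        n_control = int((df["role"] == "control").sum())
        if (n_compound, n_control) != (43, 2):
            raise ValidationError("table2 fixture must have 43 compound rows + 2 control rows")
    if name == "table3":
        n_compound = int((df["role"] == "compound").sum())
        if n_compound != 7 or len(df) != 9:
            raise ValidationError("table3 fixture must have 7 compound rows + 2 control rows")
    return PaperFixture(name=name, rows=df)


def fixture_checksum(name: str) -> str:
    """SHA-256 of the shipped fixture file, to pin it against drift."""
    if name not in _FIXTURE_NAMES:
        raise KeyError(f"unknown fixture '{name}'")
    data = _fixture_path(name).read_bytes()
    return hashlib.sha256(data).hexdigest()
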