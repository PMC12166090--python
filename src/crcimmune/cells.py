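"""Nuclei detection tables.

A :class:`CellTable` holds one slide's nucleus centroids (μm, slide space,
origin top-left, x right, y down) together with the raw classifier label,
the derived semantic class, region membership and structure/IEL flags.

Raw nucleus classes follow the seven-way H&E nuclei classification
(epithelial, lymphocyte, neutrophil, plasma, eosinophil, mitosis,
connective).  Neutrophils, plasma cells, mitoses and connective-tissue
cells are analysed as a single "other" group; epithelial nuclei stay
pending until tissue context resolves them to tumor or normal epithelium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RAW_CLASSES = (
    "epithelial",
    "lymphocyte",
    "neutrophil",
    "plasma",
    "eosinophil",
    "mitosis",
    "connective",
)

#: raw classes collapsed into the "other" analysis group
OTHER_RAW_CLASSES = frozenset({"neutrophil", "plasma", "mitosis", "connective"})

DERIVED_CLASSES = (
    "tumor_epithelial",
    "normal_epithelial",
    "lymphocyte",
    "eosinophil",
    "other",
    "epithelial_pending",  # epithelial awaiting tissue-context assignment
)

STRUCTURE_KINDS = ("none", "aggregate", "lymph_node")

REQUIRED_COLUMNS = ("slide_id", "x_um", "y_um", "class")

_STATE_COLUMNS = {
    "region": "unassigned",
    "component_id": -1,
    "structure_kind": "none",
    "is_iel": False,
    "excluded": False,
}


class DetectionFormatError(ValueError):
    """A detections file is structurally invalid (missing columns)."""


class DetectionValidationError(ValueError):
    """A detections file contains invalid values (unknown class tokens)."""


def _initial_derived(raw: pd.Series) -> pd.Series:
    derived = pd.Series("other", index=raw.index, dtype=object)
    derived[raw == "lymphocyte"] = "lymphocyte"
    derived[raw == "eosinophil"] = "eosinophil"
    derived[raw == "epithelial"] = "epithelial_pending"
    return derived


@dataclass
class CellTable:
    """Per-slide nucleus records plus slide metadata.

    The backing frame always carries the pipeline state columns
    (``derived_class``, ``region``, ``component_id``, ``structure_kind``,
    ``is_iel``, ``excluded``); stages mutate them in place.
    """

    df: pd.DataFrame
    slide_id: str = ""
    patient_id: str = ""
    cohort_id: str = ""
    front_missing: bool = field(default=False)

    def __post_init__(self) -> None:
        df = self.df
        for col in ("x_um", "y_um", "raw_class"):
            if col not in df.columns:
                raise DetectionFormatError(f"missing required column: {col}")
        if len(df) and not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
            raise DetectionValidationError("non-finite cell coordinates")
        bad = ~df["raw_class"].isin(RAW_CLASSES)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise DetectionValidationError(
                f"unknown nucleus class {df['raw_class'].iloc[idx]!r} at row {idx}"
            )
        for col, default in _STATE_COLUMNS.items():
            if col not in df.columns:
                df[col] = default
        if "front_missing" in df.columns and len(df):
            self.front_missing = bool(df["front_missing"].iloc[0])
            df.drop(columns=["front_missing"], inplace=True)
        if "derived_class" not in df.columns:
            df["derived_class"] = _initial_derived(df["raw_class"])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in μm."""
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    def mask(self, derived_class: str, include_excluded: bool = True) -> np.ndarray:
        m = (self.df["derived_class"] == derived_class).to_numpy()
        if not include_excluded:
            m &= ~self.df["excluded"].to_numpy()
        return m

    def counts_by_derived(self) -> pd.Series:
        return self.df["derived_class"].value_counts()

    def copy(self) -> "CellTable":
        return CellTable(
            self.df.copy(),
            slide_id=self.slide_id,
            patient_id=self.patient_id,
            cohort_id=self.cohort_id,
            front_missing=self.front_missing,
        )


def cell_table_from_arrays(
    x_um,
    y_um,
    raw_class,
    slide_id: str = "S1",
    patient_id: str = "P1",
    cohort_id: str = "C1",
) -> CellTable:
    """Convenience constructor used by the simulator and tests."""
    df = pd.DataFrame(
        {
            "slide_id": slide_id,
            "patient_id": patient_id,
            "cohort_id": cohort_id,
            "x_um": np.asarray(x_um, dtype=float),
            "y_um": np.asarray(y_um, dtype=float),
            "raw_class": list(raw_class),
        }
    )
    return CellTable(df, slide_id=slide_id, patient_id=patient_id, cohort_id=cohort_id)


def read_detections(path: str | Path) -> CellTable:
    """Read a single-slide detections CSV.

    The dialect is fixed: comma-delimited, UTF-8, ``.`` decimal, header row
    required with at least ``slide_id, x_um, y_um, class``.  ``patient_id``,
    ``cohort_id`` and previously written state columns are picked up when
    present.
    """
    tables = read_detections_multi(path)
    if len(tables) > 1:
        raise DetectionValidationError(
            f"expected a single slide per table, found {len(tables)} slide ids"
        )
    if not tables:
        # header-only file: empty single-slide table
        df = pd.read_csv(path, float_precision="round_trip")
        return CellTable(_normalize_frame(df), slide_id="", patient_id="", cohort_id="")
    return tables[0]


def read_detections_multi(path: str | Path) -> list[CellTable]:
    """Read a detections CSV that may contain several slides."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DetectionFormatError(f"missing required column: {missing[0]}")
    df = _normalize_frame(df)
    tables = []
    for slide_id, sub in df.groupby("slide_id", sort=True):
        sub = sub.reset_index(drop=True)
        tables.append(
            CellTable(
                sub,
                slide_id=str(slide_id),
                patient_id=str(sub["patient_id"].iloc[0]) if len(sub) else "",
                cohort_id=str(sub["cohort_id"].iloc[0]) if len(sub) else "",
            )
        )
    return tables


def _normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "class" in df.columns and "raw_class" not in df.columns:
        df = df.rename(columns={"class": "raw_class"})
    for col in ("patient_id", "cohort_id"):
        if col not in df.columns:
            df[col] = ""
    df["x_um"] = pd.to_numeric(df["x_um"])
    df["y_um"] = pd.to_numeric(df["y_um"])
    return df


def write_detections(table: CellTable, path: str | Path) -> None:
    """Write a table in the same dialect ``read_detections`` consumes.

    Coordinates round-trip bit-exactly (pandas ``repr`` float formatting).
    """
    df = table.df.copy()
    df = df.rename(columns={"raw_class": "class"})
    df["front_missing"] = table.front_missing
    lead = ["slide_id", "patient_id", "cohort_id", "x_um", "y_um", "class"]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(path, index=False)
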