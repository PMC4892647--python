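"""Table readers, run configuration, and schema validation.

All tabular inputs (CSV/TSV/xlsx) are converted on read to a canonical
in-memory schema; downstream code never sees the raw files. Blank Cq
cells mean "replicate undetected". Schema violations report the column
and the offending row number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ish import DEFAULT_MIN_ROI_MM2, DEFAULT_PIXEL_SIZE_UM
from .qpcr import DEFAULT_OUTLIER_THRESHOLD, CqTriplicate

logger = logging.getLogger(__name__)

QPCR_COLUMNS = ("patient_id", "sample_id", "deepest_flag", "mirna_id",
                "rep1_cq", "rep2_cq", "rep3_cq")
ISH_COLUMNS = ("patient_id", "sample_id", "mirna_id",
               "area_iB", "area_wB", "area_pB", "roi_area_mm2")


class SchemaError(ValueError):
    """Raised for malformed input tables, naming the column/row at fault."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_qpcr_table(path: str | Path) -> list[CqTriplicate]:
    """Read an S1-style triplicate table into CqTriplicate records.

    Blank replicate cells become undetected flags; every input row yields
    exactly one triplicate.
    """
    df = _read_table(path)
    _require_columns(df, QPCR_COLUMNS, "qPCR table")
    triplicates = []
    for idx, row in df.iterrows():
        cqs = []
        for col in ("rep1_cq", "rep2_cq", "rep3_cq"):
            cell = row[col]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                continue
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"qPCR table row {idx + 2}: non-numeric Cq in {col}: {cell!r}"
                ) from None
            if not np.isfinite(value):
                raise SchemaError(f"qPCR table row {idx + 2}: non-finite Cq in {col}")
            cqs.append(value)
        triplicates.append(
            CqTriplicate(
                patient_id=str(row["patient_id"]),
                sample_id=str(row["sample_id"]),
                mirna_id=str(row["mirna_id"]),
                replicate_cqs=tuple(cqs),
                deepest=bool(int(row["deepest_flag"])),
            )
        )
    logger.info("read %d triplicates from %s", len(triplicates), path)
    return triplicates


def read_ish_table(path: str | Path) -> pd.DataFrame:
    """Read an S2-style area table into the canonical ISH schema."""
    df = _read_table(path)
    _require_columns(df, ISH_COLUMNS, "ISH table")
    for col in ("area_iB", "area_wB", "area_pB", "roi_area_mm2"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if not bad.empty:
            raise SchemaError(
                f"ISH table row {bad.index[0] + 2}: non-numeric value in {col}"
            )
        df[col] = pd.to_numeric(df[col])
    if "deepest_flag" not in df.columns:
        df["deepest_flag"] = 0
    return df


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    qpcr_table: str = ""
    ish_table: str = ""
    out_dir: str = "mirhet_out"
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD
    min_roi_mm2: float = DEFAULT_MIN_ROI_MM2
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    color_centroids: dict = field(default_factory=dict)
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        for name in ("outlier_threshold", "min_roi_mm2", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def write_csv(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a report with a fixed float format so reruns are byte-identical."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)
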