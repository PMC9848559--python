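"""Readers and writers for the pipeline's file dialects.

Consumer files: CSV with headers exactly ``D13C, D15N`` (one row per
individual).  Source files: the 11-column source dialect
(Sources, Meand13C, ..., conc15N).  Diet table: reservoir metadata plus
the 12 diet-category columns of species-level mean volumetric
proportions.  Predation matrix: prey rows × predator columns, first
column the taxon label.  All readers are strict about headers; writers
round-trip losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import DIET_TABLE_META_COLUMNS, SOURCE_FILE_COLUMNS
from .types import DIET_CATEGORIES, IsotopeSample, PredationMatrix, SourceSpec

log = logging.getLogger("isoweb")


class DialectError(ValueError):
    """A file does not conform to the expected column dialect."""


def read_consumer_file(path: str | Path, taxon: str | None = None) -> list[IsotopeSample]:
    """Read one consumer isotope file (columns D13C, D15N)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("D13C", "D15N"):
        if col not in df.columns:
            raise DialectError(
                f"{path}: missing required header {col!r} "
                f"(found {list(df.columns)})"
            )
    extra = [c for c in df.columns if c not in ("D13C", "D15N")]
    if extra:
        log.warning("%s: ignoring extra columns %s", path, extra)
    taxon = taxon or path.stem
    samples = []
    for i, row in df.iterrows():
        try:
            c, n = float(row["D13C"]), float(row["D15N"])
        except (TypeError, ValueError) as exc:
            raise DialectError(f"{path}: non-numeric value in row {i + 2}") from exc
        if np.isnan(c) or np.isnan(n):
            raise DialectError(f"{path}: missing value in row {i + 2}")
        samples.append(IsotopeSample(taxon, c, n))
    return samples


def write_consumer_file(samples: list[IsotopeSample], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"D13C": [s.d13C for s in samples], "D15N": [s.d15N for s in samples]}
    ).to_csv(path, index=False)
    return path


def read_sources_file(path: str | Path) -> list[SourceSpec]:
    """Read one source file in the 11-column dialect; conc columns optional."""
    path = Path(path)
    df = pd.read_csv(path)
    required = SOURCE_FILE_COLUMNS[:9]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing source columns {missing}")
    has_conc = all(c in df.columns for c in ("conc13C", "conc15N"))
    if not has_conc:
        log.info("%s: no concentration columns; defaulting to 1.0", path)
    specs = []
    for i, row in df.iterrows():
        for sd_col in ("SDd13C", "SDd15N", "tefSDd13C", "tefSDd15N"):
            if float(row[sd_col]) < 0:
                raise DialectError(
                    f"{path}: negative SD in column {sd_col}, row {i + 2}"
                )
        specs.append(
            SourceSpec(
                name=str(row["Sources"]),
                mean_d13C=float(row["Meand13C"]),
                sd_d13C=float(row["SDd13C"]),
                mean_d15N=float(row["Meand15N"]),
                sd_d15N=float(row["SDd15N"]),
                tef_d13C=float(row["tefd13C"]),
                tef_sd_d13C=float(row["tefSDd13C"]),
                tef_d15N=float(row["tefd15N"]),
                tef_sd_d15N=float(row["tefSDd15N"]),
                conc_C=float(row["conc13C"]) if has_conc else 1.0,
                conc_N=float(row["conc15N"]) if has_conc else 1.0,
            )
        )
    return specs


def write_sources_file(specs: list[SourceSpec], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "Sources": s.name,
            "Meand13C": s.mean_d13C,
            "SDd13C": s.sd_d13C,
            "Meand15N": s.mean_d15N,
            "SDd15N": s.sd_d15N,
            "tefd13C": s.tef_d13C,
            "tefSDd13C": s.tef_sd_d13C,
            "tefd15N": s.tef_d15N,
            "tefSDd15N": s.tef_sd_d15N,
            "conc13C": s.conc_C,
            "conc15N": s.conc_N,
        }
        for s in specs
    ]
    pd.DataFrame(rows, columns=SOURCE_FILE_COLUMNS).to_csv(path, index=False)
    return path


@dataclass
class DietTable:
    """Species-level mean-VO diet table plus validation flags."""

    data: pd.DataFrame
    flagged_rows: list[int] = field(default_factory=list)  # diet sum off 1
    below_minimum: list[str] = field(default_factory=list)  # < 4 replicates


def read_diet_table(path: str | Path, min_replicates: int = 4) -> DietTable:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in DIET_TABLE_META_COLUMNS if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing metadata columns {missing}")
    missing = [c for c in DIET_CATEGORIES if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing diet columns {missing}")
    diet_cols = [c for c in df.columns if c not in DIET_TABLE_META_COLUMNS]
    sums = df[diet_cols].sum(axis=1)
    flagged = [int(i) for i in df.index[(sums < 0.98) | (sums > 1.02)]]
    if flagged:
        log.warning("%s: rows %s have diet sums outside [0.98, 1.02]", path, flagged)
    below = [
        str(r["Fish species"])
        for _, r in df.iterrows()
        if int(r["Replicates"]) < min_replicates
    ]
    return DietTable(data=df, flagged_rows=flagged, below_minimum=below)


def read_gut_records(path: str | Path):
    """Read per-gut long-format records (species, gut_id, category, proportion)."""
    from .types import GutRecord

    df = pd.read_csv(path)
    required = {"species", "gut_id", "category", "proportion"}
    missing = required - set(df.columns)
    if missing:
        raise DialectError(f"{path}: missing gut-record columns {sorted(missing)}")
    records = []
    for (species, gut_id), grp in df.groupby(["species", "gut_id"], sort=True):
        comp = dict(zip(grp["category"].astype(str), grp["proportion"].astype(float)))
        records.append(GutRecord(str(species), str(gut_id), comp))
    return records


def read_predation_matrix(path: str | Path) -> PredationMatrix:
    df = pd.read_csv(path, index_col=0)
    return PredationMatrix(df.astype(float))


def write_predation_matrix(matrix: PredationMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.values.to_csv(path, index_label="taxon")
    return path


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DialectError(f"{path}: YAML config must be a mapping")
    return cfg


def convert_xlsx(path: str | Path, outdir: str | Path) -> list[Path]:
    """Convert each sheet of an Excel workbook to CSV (read-only support)."""
    path, outdir = Path(path), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheets = pd.read_excel(path, sheet_name=None)
    written = []
    for name, df in sheets.items():
        safe = name.replace("/", "_").replace(" ", "_")
        out = outdir / f"{path.stem}.{safe}.csv"
        df.to_csv(out, index=False)
        written.append(out)
    return written


__all__ = [
    "DialectError",
    "read_consumer_file",
    "write_consumer_file",
    "read_sources_file",
    "write_sources_file",
    "DietTable",
    "read_diet_table",
    "read_gut_records",
    "read_predation_matrix",
    "write_predation_matrix",
    "load_yaml_config",
    "convert_xlsx",
]
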