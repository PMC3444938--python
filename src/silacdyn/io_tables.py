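"""Tabular I/O: protein-group TSV, metabolite fragment TSV, metadata YAML.

All tables are strict, dot-decimal, unquoted TSV (the dialect MaxQuant and
MetMax emit).  Sample-resolved columns use the ``<field>.<sample_id>``
suffix convention; the sample metadata itself travels separately in YAML.
Missing ratios are kept missing — read as ``None``, written as an empty
cell — never imputed as zero.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass, asdict
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "SampleMeta",
    "SampleQuant",
    "ProteinQuant",
    "MetaboliteTable",
    "read_metadata",
    "write_metadata",
    "read_protein_groups",
    "write_protein_groups",
    "read_metabolite_table",
    "write_metabolite_table",
    "write_results",
    "read_results",
]

#: Maximum heavy-minus-light fragment mass shift: arginine carries at most
#: six heavy carbons, so no downstream fragment can shift by more.
MAX_MASS_SHIFT = 6

_MISSING_TOKENS = {"", "nan", "NaN", "NA"}


class SchemaError(ValueError):
    """A required column is absent or a cell violates the schema."""


@dataclass(frozen=True)
class SampleMeta:
    """One experimental sample: time point, salt condition, replicate."""

    sample_id: str
    time_h: float
    nacl_mM: float = 0.0
    replicate: int = 1
    cell_count: Optional[float] = None
    internal_standard: Optional[float] = None

    def __post_init__(self):
        if self.time_h < 0:
            raise ValueError(f"{self.sample_id}: time_h must be non-negative")
        if self.nacl_mM < 0:
            raise ValueError(f"{self.sample_id}: nacl_mM must be non-negative")
        if self.replicate < 1:
            raise ValueError(f"{self.sample_id}: replicate must be a positive integer")
        if self.cell_count is not None and self.cell_count <= 0:
            raise ValueError(f"{self.sample_id}: cell_count must be positive")


@dataclass
class SampleQuant:
    """Per-sample quantification block of one protein."""

    ratio_hl: Optional[float] = None
    ratio_count: int = 0
    intensity: float = 0.0
    unique_peptides: int = 0
    intensity_l: Optional[float] = None
    intensity_h: Optional[float] = None

    def __post_init__(self):
        if self.ratio_count == 0 and self.ratio_hl is not None:
            raise ValueError("ratio_hl present but ratio_count is 0")
        if self.ratio_hl is not None and self.ratio_hl < 0:
            raise ValueError("ratio_hl must be non-negative")


@dataclass
class ProteinQuant:
    """One protein group with per-sample quantifications."""

    protein_id: str
    molecular_mass: float
    description: str = ""
    mapman_bin: str = ""
    samples: dict = field(default_factory=dict)  # sample_id -> SampleQuant

    def __post_init__(self):
        if self.molecular_mass <= 0:
            raise ValueError(f"{self.protein_id}: molecular_mass must be positive")


@dataclass
class MetaboliteTable:
    """GC-MS fragment-pair intensities.

    ``data`` has one row per declared fragment pair with columns
    ``metabolite``, ``derivative``, ``light_mz``, ``heavy_mz`` and, per
    sample, ``light.<sid>`` / ``heavy.<sid>`` intensity columns.
    """

    data: pd.DataFrame
    sample_ids: List[str]

    def __post_init__(self):
        bad = self.data[self.data["heavy_mz"] <= self.data["light_mz"]]
        if len(bad):
            m = bad.iloc[0]
            raise SchemaError(
                f"{m['metabolite']}: heavy m/z {m['heavy_mz']} not greater than "
                f"light m/z {m['light_mz']}"
            )
        shift = self.data["heavy_mz"] - self.data["light_mz"]
        bad = self.data[shift > MAX_MASS_SHIFT]
        if len(bad):
            m = bad.iloc[0]
            raise SchemaError(
                f"{m['metabolite']}: mass shift {int(m['heavy_mz'] - m['light_mz'])} "
                f"exceeds {MAX_MASS_SHIFT} heavy carbons"
            )

    def intensities(self, sample_id: str) -> pd.DataFrame:
        if sample_id not in self.sample_ids:
            raise KeyError(f"unknown sample {sample_id!r}")
        out = self.data[["metabolite", "derivative", "light_mz", "heavy_mz"]].copy()
        out["light"] = self.data[f"light.{sample_id}"]
        out["heavy"] = self.data[f"heavy.{sample_id}"]
        return out


# ---------------------------------------------------------------------------
# metadata YAML

def read_metadata(path: os.PathLike | str) -> List[SampleMeta]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, Mapping) and "samples" in raw:
        raw = raw["samples"]
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: expected a list of sample entries")
    metas = [SampleMeta(**entry) for entry in raw]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise SchemaError(f"duplicate sample_id {dup!r} in metadata")
    return metas


def write_metadata(metas: Sequence[SampleMeta], path: os.PathLike | str) -> None:
    entries = []
    for m in metas:
        d = {k: v for k, v in asdict(m).items() if v is not None}
        entries.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump({"samples": entries}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# protein groups

_PG_FIXED = ["protein_id", "molecular_mass"]
_PG_OPTIONAL = ["description", "mapman_bin"]
_PG_PER_SAMPLE = ["ratio_hl", "ratio_count", "intensity", "unique_peptides"]
_PG_PER_SAMPLE_OPT = ["intensity_l", "intensity_h"]


def _parse_float(cell: str, row: int, col: str, allow_missing: bool) -> Optional[float]:
    s = cell.strip() if isinstance(cell, str) else cell
    if s is None or (isinstance(s, float) and math.isnan(s)) or s in _MISSING_TOKENS:
        if allow_missing:
            return None
        raise SchemaError(f"row {row}, column {col!r}: missing value not allowed")
    try:
        return float(s)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}, column {col!r}: cannot parse {cell!r} as number") from None


def _parse_int(cell: str, row: int, col: str) -> int:
    v = _parse_float(cell, row, col, allow_missing=False)
    if v != int(v):
        raise SchemaError(f"row {row}, column {col!r}: expected integer, got {cell!r}")
    return int(v)


def read_protein_groups(
    path: os.PathLike | str, metadata: Sequence[SampleMeta]
) -> List[ProteinQuant]:
    """Read a MaxQuant-style protein-group TSV.

    Per-sample columns are ``ratio_hl.<sid>``, ``ratio_count.<sid>``,
    ``intensity.<sid>`` and ``unique_peptides.<sid>`` for every sample_id
    in ``metadata``.  Missing ratios (empty cell or ``NaN``) are read as
    ``None`` with a ratio count of 0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _PG_FIXED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    # samples entirely absent from the table (e.g. metabolomics-only runs
    # sharing the metadata file) are skipped; a partial block is an error
    present: List[SampleMeta] = []
    for meta in metadata:
        cols = [f"{f}.{meta.sample_id}" for f in _PG_PER_SAMPLE]
        have = [c for c in cols if c in df.columns]
        if not have:
            continue
        for col in cols:
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column {col!r}")
        present.append(meta)
    metadata = present

    proteins: List[ProteinQuant] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        pid = rec["protein_id"].strip()
        if pid in seen:
            raise SchemaError(f"duplicate protein_id {pid!r}")
        seen.add(pid)
        mass = _parse_float(rec["molecular_mass"], i, "molecular_mass", False)
        samples = {}
        for meta in metadata:
            sid = meta.sample_id
            ratio = _parse_float(rec[f"ratio_hl.{sid}"], i, f"ratio_hl.{sid}", True)
            rc = _parse_int(rec[f"ratio_count.{sid}"], i, f"ratio_count.{sid}")
            if rc == 0:
                ratio = None
            samples[sid] = SampleQuant(
                ratio_hl=ratio,
                ratio_count=rc,
                intensity=_parse_float(rec[f"intensity.{sid}"], i, f"intensity.{sid}", False),
                unique_peptides=_parse_int(
                    rec[f"unique_peptides.{sid}"], i, f"unique_peptides.{sid}"
                ),
                intensity_l=_parse_float(rec.get(f"intensity_l.{sid}", ""), i, f"intensity_l.{sid}", True),
                intensity_h=_parse_float(rec.get(f"intensity_h.{sid}", ""), i, f"intensity_h.{sid}", True),
            )
        proteins.append(
            ProteinQuant(
                protein_id=pid,
                molecular_mass=mass,
                description=rec.get("description", ""),
                mapman_bin=rec.get("mapman_bin", ""),
                samples=samples,
            )
        )
    return proteins


def write_protein_groups(
    proteins: Sequence[ProteinQuant],
    metadata: Sequence[SampleMeta],
    path: os.PathLike | str,
) -> None:
    rows = []
    have_channels = any(
        sq.intensity_l is not None for p in proteins for sq in p.samples.values()
    )
    for p in proteins:
        row = {
            "protein_id": p.protein_id,
            "description": p.description,
            "mapman_bin": p.mapman_bin,
            "molecular_mass": p.molecular_mass,
        }
        for meta in metadata:
            sid = meta.sample_id
            sq = p.samples.get(sid, SampleQuant())
            row[f"ratio_hl.{sid}"] = "" if sq.ratio_hl is None else sq.ratio_hl
            row[f"ratio_count.{sid}"] = sq.ratio_count
            row[f"intensity.{sid}"] = sq.intensity
            row[f"unique_peptides.{sid}"] = sq.unique_peptides
            if have_channels:
                row[f"intensity_l.{sid}"] = "" if sq.intensity_l is None else sq.intensity_l
                row[f"intensity_h.{sid}"] = "" if sq.intensity_h is None else sq.intensity_h
        rows.append(row)
    write_results(rows, path)


# ---------------------------------------------------------------------------
# metabolite table

def read_metabolite_table(
    path: os.PathLike | str, metadata: Sequence[SampleMeta]
) -> MetaboliteTable:
    """Read a MetMax-style fragment-pair intensity TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ["metabolite", "derivative", "light_mz", "heavy_mz"]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    known = {m.sample_id for m in metadata}
    sample_ids = []
    for col in df.columns:
        if col.startswith(("light.", "heavy.")):
            _, sid = col.split(".", 1)
            if sid not in known:
                raise SchemaError(f"{path}: column {col!r} refers to unknown sample {sid!r}")
            if sid not in sample_ids:
                sample_ids.append(sid)
    for sid in sample_ids:
        for side in ("light", "heavy"):
            if f"{side}.{sid}" not in df.columns:
                raise SchemaError(f"{path}: missing column '{side}.{sid}'")

    out = pd.DataFrame(
        {
            "metabolite": df["metabolite"].str.strip(),
            "derivative": df["derivative"].str.strip(),
            "light_mz": [_parse_int(v, i + 2, "light_mz") for i, v in enumerate(df["light_mz"])],
            "heavy_mz": [_parse_int(v, i + 2, "heavy_mz") for i, v in enumerate(df["heavy_mz"])],
        }
    )
    for sid in sample_ids:
        for side in ("light", "heavy"):
            col = f"{side}.{sid}"
            out[col] = [
                _parse_float(v, i + 2, col, allow_missing=False)
                for i, v in enumerate(df[col])
            ]
    return MetaboliteTable(data=out, sample_ids=sample_ids)


def write_metabolite_table(table: MetaboliteTable, path: os.PathLike | str) -> None:
    write_results(table.data.to_dict("records"), path)


# ---------------------------------------------------------------------------
# generic results TSV

def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise ValueError("cannot write an empty table")
        return records.copy()
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record list")
    first = records[0]
    if is_dataclass(first):
        names = [f.name for f in dc_fields(first)]
        rows = []
        for r in records:
            if [f.name for f in dc_fields(r)] != names:
                raise ValueError("records are not homogeneous")
            rows.append({n: getattr(r, n) for n in names})
        return pd.DataFrame(rows, columns=names)
    if isinstance(first, Mapping):
        names = list(first.keys())
        for r in records:
            if list(r.keys()) != names:
                raise ValueError("records are not homogeneous")
        return pd.DataFrame(records, columns=names)
    raise TypeError(f"unsupported record type {type(first).__name__}")


def write_results(records, path: os.PathLike | str) -> None:
    """Write records as strict TSV: header row, empty cell for missing.

    Embedded tab or newline characters are rejected rather than quoted, so
    every written file re-reads unambiguously.  Raises before any file is
    created on empty input.
    """
    df = _records_to_frame(records)
    for col in df.columns:
        if "\t" in str(col) or "\n" in str(col):
            raise ValueError(f"column name {col!r} contains a tab or newline")
        if df[col].dtype == object:
            for v in df[col]:
                if isinstance(v, str) and ("\t" in v or "\n" in v):
                    raise ValueError(
                        f"value {v!r} in column {col!r} contains a tab or newline; "
                        "strict TSV dialect does not quote"
                    )
    df = df.where(pd.notna(df), "")
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_results(path: os.PathLike | str) -> pd.DataFrame:
    """Read back a results TSV; empty cells become NaN/None."""
    return pd.read_csv(path, sep="\t", na_values=[""], keep_default_na=True)
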