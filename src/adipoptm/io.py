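"""Readers and writers for the tabular formats used throughout the pipeline.

All matrices travel as :class:`IntensityMatrix`: a features x samples
:class:`pandas.DataFrame` plus an explicit scale flag (``"raw"`` or
``"log2"``).  The scale is never guessed from the numbers.  Missing cells
are ``NaN``; on the raw scale an intensity of 0 means "not detected" and is
parsed as missing.

Formats
-------
* intensity TSV — first column = feature ID, header = sample IDs, empty
  cell / ``NA`` / ``NaN`` = missing; lines starting with ``#`` are
  provenance comments and are skipped,
* design TSV — columns ``sample_id``, ``condition``, ``time_code``,
  ``replicate``,
* GMT — one gene set per line: name, description, tab-separated members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}

DESIGN_COLUMNS = ("sample_id", "condition", "time_code", "replicate")


@dataclass
class IntensityMatrix:
    """Feature x sample abundance matrix with explicit missingness."""

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        dup_f = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup_f:
            raise ValueError(f"duplicate feature IDs: {dup_f}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample IDs: {dup_s}")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(arr).any():
            raise ValueError("intensity values must be finite where present")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.scale)


@dataclass
class GeneSetCollection:
    """Named gene sets over protein identifiers, with an optional explicit
    background universe."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    universe: list[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}


def _parse_cell(token: str, scale: str, path: str, row_id: str, col: str) -> float:
    stripped = token.strip()
    if stripped.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        value = float(stripped)
    except ValueError as exc:
        raise ValueError(
            f"{path}: non-numeric cell {token!r} at feature {row_id!r}, sample {col!r}"
        ) from exc
    if scale == RAW and value == 0.0:
        return math.nan  # raw intensity 0 = not detected
    if math.isinf(value):
        raise ValueError(f"{path}: infinite value at feature {row_id!r}, sample {col!r}")
    return value


def read_intensity_table(path: str | Path, scale: str) -> IntensityMatrix:
    """Read a feature x sample TSV into an :class:`IntensityMatrix`.

    ``scale`` must be declared by the caller ("raw" or "log2").  Empty
    cells, ``NA``/``NaN`` tokens and — on the raw scale only — zeros are
    parsed as missing.  Duplicate feature IDs and non-numeric cells raise
    ``ValueError`` with the offending location.
    """
    path = Path(path)
    if scale not in (RAW, LOG2):
        raise ValueError(f"scale must be 'raw' or 'log2', got {scale!r}")
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty intensity table")
    header = lines[0].split("\t")
    samples = header[1:]
    if not samples:
        raise ValueError(f"{path}: header has no sample columns")
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        fid = fields[0]
        feature_ids.append(fid)
        rows.append([_parse_cell(tok, scale, str(path), fid, samples[j])
                     for j, tok in enumerate(fields[1:])])
    seen: set[str] = set()
    dups = sorted({f for f in feature_ids if f in seen or seen.add(f)})
    if dups:
        raise ValueError(f"{path}: duplicate feature IDs: {dups}")
    values = pd.DataFrame(rows, index=feature_ids, columns=samples, dtype=float)
    return IntensityMatrix(values, scale)


def write_intensity_table(matrix: IntensityMatrix, path: str | Path,
                          provenance: str | None = None) -> None:
    """Write an intensity matrix as TSV; missing cells become empty strings.

    Values are written with full float precision so a write -> read round
    trip is exact.
    """
    path = Path(path)
    with open(path, "w") as handle:
        if provenance:
            handle.write(f"# {provenance}\n")
        handle.write("feature_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for fid, row in matrix.values.iterrows():
            cells = ["" if math.isnan(v) else format(v, ".17g") for v in row]
            handle.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design table (sample_id, condition, time_code, replicate)."""
    path = Path(path)
    design = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"{path}: design table missing columns {missing}")
    design = design[list(DESIGN_COLUMNS)].copy()
    design["time_code"] = design["time_code"].astype(int)
    design["replicate"] = design["replicate"].astype(int)
    dups = design["sample_id"][design["sample_id"].duplicated()].tolist()
    if dups:
        raise ValueError(f"{path}: duplicate sample IDs in design: {dups}")
    return design.reset_index(drop=True)


def write_design(design: pd.DataFrame, path: str | Path,
                 provenance: str | None = None) -> None:
    with open(path, "w") as handle:
        if provenance:
            handle.write(f"# {provenance}\n")
        design.to_csv(handle, sep="\t", index=False)


def check_design(matrix: IntensityMatrix, design: pd.DataFrame) -> None:
    """Every matrix sample must appear exactly once in the design."""
    design_samples = list(design["sample_id"])
    missing = [s for s in matrix.sample_ids if s not in design_samples]
    if missing:
        raise ValueError(f"samples absent from design: {missing}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Members are deduplicated within a set (first occurrence wins).  A line
    with fewer than 3 tab-separated fields is an error reported with its
    line number.  An empty file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields (name, "
                    f"description, members), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as handle:
        for name, members in collection.sets.items():
            desc = (descriptions or {}).get(name, "na")
            handle.write("\t".join([name, desc, *members]) + "\n")
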