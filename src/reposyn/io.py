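"""Text-format I/O: GCT v1.2 matrices, GMT gene sets, and the TSV tables
used by the pipeline (dose-response plates, condition metadata, sample sheets).

All writers emit plain text; numeric values are written with 10 significant
digits so a write/read round trip reproduces matrices exactly at that
precision. Readers validate structure and raise :class:`ParseError` naming
the offending line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import InputError, ParseError

_FLOAT_FMT = "%.10g"

DOSE_RESPONSE_COLUMNS = [
    "cell_line",
    "drug1",
    "dose1",
    "drug2",
    "dose2",
    "replicate",
    "viability_pct",
]

METADATA_COLUMNS = ["condition_id", "perturbagen", "cell_line", "dose", "time"]


# ---------------------------------------------------------------------------
# GCT v1.2
# ---------------------------------------------------------------------------

def write_gct(matrix: pd.DataFrame, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write a genes x samples DataFrame as a GCT v1.2 text file.

    The DataFrame index holds gene identifiers (row NAME column); the
    Description column is filled from *descriptions* or left as "na".
    """
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene ids cannot be written to GCT: {dupes[:5]}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gene, row in matrix.iterrows():
            desc = descriptions.get(gene, "na") if descriptions else "na"
            vals = "\t".join(_FLOAT_FMT % v for v in row.to_numpy())
            fh.write(f"{gene}\t{desc}\t{vals}\n")


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT v1.2 file into a genes x samples DataFrame.

    Header dimensions are validated against the body; duplicate gene ids and
    row-length mismatches raise :class:`ParseError` with the line number.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#1.2"):
        raise ParseError(f"{path}: line 1: expected GCT version line '#1.2'")
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GCT file ({len(lines)} lines)")
    dims = lines[1].split("\t")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 2: malformed dimension line {lines[1]!r}") from None
    header = lines[2].split("\t")
    if len(header) != n_cols + 2:
        raise ParseError(
            f"{path}: line 3: header has {len(header) - 2} sample columns, "
            f"dimension line declares {n_cols}")
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_rows:
        raise ParseError(
            f"{path}: body has {len(body)} data rows, dimension line declares {n_rows}")
    genes, rows = [], []
    for i, ln in enumerate(body, start=4):
        parts = ln.split("\t")
        if len(parts) != n_cols + 2:
            raise ParseError(
                f"{path}: line {i}: expected {n_cols + 2} fields, found {len(parts)}")
        genes.append(parts[0])
        try:
            rows.append([float(v) for v in parts[2:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-numeric value ({exc})") from None
    df = pd.DataFrame(rows, index=genes, columns=header[2:])
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids: {dupes[:5]}")
    return df


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    """Write named gene sets as GMT (one set per line: name, description, members)."""
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([str(name), description, *map(str, genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping set name -> member list."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {i}: GMT record needs name, description and "
                    f"at least one gene ({len(parts)} fields found)")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}: line {i}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", quoting=csv.QUOTE_NONE)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_dose_response(path: str | Path) -> pd.DataFrame:
    """Read a dose-response plate TSV (columns as in DOSE_RESPONSE_COLUMNS)."""
    df = _read_tsv(path, DOSE_RESPONSE_COLUMNS)
    df["drug2"] = df["drug2"].fillna("")
    if (df["viability_pct"] < 0).any():
        raise InputError(f"{path}: negative viability_pct values present")
    if ((df["dose1"] <= 0) & (df["dose2"] <= 0)).any():
        raise InputError(f"{path}: rows with no positive dose present")
    return df


def write_dose_response(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_condition_metadata(path: str | Path) -> pd.DataFrame:
    """Read compendium condition metadata (condition_id, perturbagen, cell_line, dose, time)."""
    df = _read_tsv(path, METADATA_COLUMNS)
    if df["condition_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate condition_id values")
    return df.set_index("condition_id", drop=False)


def write_condition_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, group) into a Series sample -> group."""
    df = _read_tsv(path, ["sample_id", "group"])
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id values")
    return df.set_index("sample_id")["group"]
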