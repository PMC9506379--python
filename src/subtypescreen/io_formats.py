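"""Readers and writers for the tabular and set formats the pipeline touches.

GCT v1.2 matrices (the Broad convention for expression and drug-response
tables), GMT/GMX set collections (row-per-set and column-per-set dialects
of the same logical structure), and plain delimited tables for annotations.

Missing values: ``""``, ``"NA"`` and ``"NaN"`` (any case) are accepted on
read; ``"NA"`` is written.  Identifiers are case-sensitive and
whitespace-stripped — drug names in screens differ only by salt suffixes,
so silent case-folding would merge distinct compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_MISSING_TOKENS = {"", "na", "nan"}


class FormatError(ValueError):
    """A file violates the format it claims to be in."""


@dataclass
class GctMatrix:
    """A GCT v1.2 matrix: rows × columns of floats with row descriptions."""

    row_ids: list[str]
    column_ids: list[str]
    values: np.ndarray  # shape (n_rows, n_cols), NaN marks missing
    row_descriptions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.row_descriptions:
            self.row_descriptions = ["na"] * len(self.row_ids)
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("duplicate row ids")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise FormatError("duplicate column ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.column_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids × {len(self.column_ids)} column ids"
            )
        if len(self.row_descriptions) != len(self.row_ids):
            raise FormatError("row_descriptions length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, descriptions: list[str] | None = None) -> "GctMatrix":
        return cls(
            row_ids=[str(i) for i in frame.index],
            column_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            row_descriptions=descriptions or [],
        )


@dataclass
class SetCollection:
    """Named identifier sets (drug sets, gene signatures) with descriptions."""

    names: list[str]
    members: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise FormatError(f"duplicate set name(s): {sorted(dupes)}")
        for name in self.names:
            if not self.members.get(name):
                raise FormatError(f"set {name!r} is empty")
        for name in self.names:
            self.descriptions.setdefault(name, "na")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> list[str]:
        return self.members[name]


def _parse_cell(token: str) -> float:
    tok = token.strip()
    if tok.lower() in _MISSING_TOKENS:
        return np.nan
    return float(tok)


def read_gct(path) -> GctMatrix:
    """Read a GCT v1.2 file.

    The file must start with a ``#1.2`` version line followed by a
    tab-separated ``n_rows\\tn_cols`` dimensions line; the declared
    dimensions must match the body.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        got = lines[0] if lines else "<empty file>"
        raise FormatError(f"not a GCT 1.2 file: first line is {got!r}, expected '#1.2'")
    if len(lines) < 3:
        raise FormatError("truncated GCT: missing dimensions or header line")
    dims = lines[1].split("\t")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise FormatError(f"malformed dimensions line: {lines[1]!r}") from None
    header = lines[2].split("\t")
    if len(header) != 2 + n_cols:
        raise FormatError(
            f"header declares {len(header) - 2} columns, dimensions line declares {n_cols}"
        )
    column_ids = [c.strip() for c in header[2:]]
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_rows:
        raise FormatError(f"dimensions line declares {n_rows} rows, file contains {len(body)}")
    row_ids, row_desc = [], []
    values = np.empty((n_rows, n_cols))
    for i, line in enumerate(body):
        fields = line.split("\t")
        if len(fields) != 2 + n_cols:
            raise FormatError(f"row {i + 1} has {len(fields) - 2} data cells, expected {n_cols}")
        row_ids.append(fields[0].strip())
        row_desc.append(fields[1].strip())
        try:
            values[i] = [_parse_cell(tok) for tok in fields[2:]]
        except ValueError:
            raise FormatError(f"non-numeric cell in data row {i + 1}: {line!r}") from None
    return GctMatrix(row_ids, column_ids, values, row_desc)


def write_gct(matrix: GctMatrix, path) -> str:
    """Write a GCT v1.2 file; NaN cells are written as ``NA``."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(matrix.row_ids)}\t{len(matrix.column_ids)}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.column_ids) + "\n")
        for rid, desc, row in zip(matrix.row_ids, matrix.row_descriptions, matrix.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(rid + "\t" + desc + "\t" + "\t".join(cells) + "\n")
    return str(path)


def read_sets(path, dialect: str = "gmt") -> SetCollection:
    """Read a set collection in GMT (row-per-set) or GMX (column-per-set) form.

    Both dialects carry a name, a description, and members; blank member
    cells are dropped.  The logical collection is dialect-independent.
    """
    if dialect not in ("gmt", "gmx"):
        raise ValueError(f"dialect must be 'gmt' or 'gmx', got {dialect!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if dialect == "gmx":
        # transpose: column j holds (name, description, members...)
        width = max(len(r) for r in rows)
        padded = [r + [""] * (width - len(r)) for r in rows]
        rows = [list(col) for col in zip(*padded)]
    names, members, descriptions = [], {}, {}
    for row in rows:
        if len(row) < 2:
            raise FormatError(f"set record too short: {row!r}")
        name = row[0].strip()
        if name in members:
            raise FormatError(f"duplicate set name: {name!r}")
        kept = [tok.strip() for tok in row[2:] if tok.strip()]
        if not kept:
            raise FormatError(f"set {name!r} is empty after dropping blank members")
        names.append(name)
        members[name] = kept
        descriptions[name] = row[1].strip()
    return SetCollection(names, members, descriptions)


def write_sets(collection: SetCollection, path, dialect: str = "gmt") -> str:
    """Write a set collection as GMT or GMX."""
    if dialect not in ("gmt", "gmx"):
        raise ValueError(f"dialect must be 'gmt' or 'gmx', got {dialect!r}")
    records = [
        [name, collection.descriptions[name]] + list(collection.members[name])
        for name in collection.names
    ]
    if dialect == "gmx":
        depth = max(len(r) for r in records)
        padded = [r + [""] * (depth - len(r)) for r in records]
        records = [list(row) for row in zip(*padded)]
    with open(path, "wt", encoding="utf-8") as fh:
        for rec in records:
            fh.write("\t".join(rec) + "\n")
    return str(path)


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a delimited annotation/survival/subtype-call table with a header row."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(frame: pd.DataFrame, path, **kwargs) -> str:
    frame.to_csv(path, sep="\t", index=False, **kwargs)
    return str(path)
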