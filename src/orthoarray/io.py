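"""Readers and writers for the external formats the pipeline touches.

Formats: transcript FASTA (``gene=`` header convention, optionally a
separate two-column transcript→gene TSV), Affymetrix-style tab-separated
probe tables, ASCII CEL version-3 intensity files, GMT gene sets, and
plain TSV expression matrices.  All coordinates are 0-based with
``x`` = column and ``y`` = row, matching the CEL text convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "TranscriptRecord",
    "ProbeTableRow",
    "IntensityMatrix",
    "read_fasta",
    "write_fasta",
    "read_gene_map",
    "read_probe_tab",
    "write_probe_tab",
    "read_cel_text",
    "write_cel_text",
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
]

_DNA = set("ACGTN")
_PROBE_ALPHABET = set("ACGT")

PROBE_TAB_COLUMNS = [
    "probeset_id",
    "probe_id",
    "x",
    "y",
    "interrogation_position",
    "sequence",
    "role",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One cDNA sequence with its gene assignment."""

    transcript_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"transcript {self.transcript_id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise FormatError(
                f"transcript {self.transcript_id!r}: non-ACGTN characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class ProbeTableRow:
    """One 25-mer oligo of a probe pair.

    ``probe_id`` identifies the probe *pair*; the PM and MM oligos of a
    pair share it and differ in ``role``.
    """

    probeset_id: str
    probe_id: str
    x: int
    y: int
    interrogation_position: int
    sequence: str
    role: str  # "PM" | "MM"

    def __post_init__(self) -> None:
        if len(self.sequence) != 25:
            raise FormatError(
                f"probe {self.probe_id!r}: sequence length {len(self.sequence)} != 25"
            )
        bad = set(self.sequence) - _PROBE_ALPHABET
        if bad:
            raise FormatError(f"probe {self.probe_id!r}: non-ACGT characters {sorted(bad)}")
        if self.role not in ("PM", "MM"):
            raise FormatError(f"probe {self.probe_id!r}: role must be PM or MM")


class IntensityMatrix:
    """Per-cell intensities for one or more arrays sharing a grid.

    ``values`` has shape ``(n_samples, rows, cols)``; the intensity of the
    cell at grid position (x, y) of sample ``s`` is ``values[s, y, x]``.
    All intensities are strictly positive.
    """

    def __init__(self, sample_ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError("values must have shape (n_samples, rows, cols)")
        if len(sample_ids) != values.shape[0]:
            raise ValueError("sample_ids length does not match values")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(values > 0):
            raise ValueError("intensities must be strictly positive")
        self.sample_ids = list(sample_ids)
        self.values = values

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dims(self) -> tuple[int, int]:
        """(rows, cols) of the grid."""
        return self.values.shape[1], self.values.shape[2]

    def sample(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    @classmethod
    def from_cels(cls, paths: Sequence[str | os.PathLike]) -> "IntensityMatrix":
        """Stack several single-sample CEL files; grids must agree."""
        singles = [read_cel_text(p) for p in paths]
        dims = {m.dims for m in singles}
        if len(dims) > 1:
            raise FormatError(f"CEL grid dimensions differ across samples: {sorted(dims)}")
        values = np.concatenate([m.values for m in singles], axis=0)
        ids = [sid for m in singles for sid in m.sample_ids]
        return cls(ids, values)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | os.PathLike,
    gene_map: Mapping[str, str] | None = None,
) -> list[TranscriptRecord]:
    """Read a transcript FASTA.

    Gene assignments come from a ``gene=<id>`` token in the header; an
    explicit ``gene_map`` (transcript_id → gene_id) overrides the header
    where both are present.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        tid = rec.id
        if tid in seen:
            raise FormatError(f"duplicate transcript id {tid!r}")
        seen.add(tid)
        gene = None
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene = token[len("gene=") :]
        if gene_map is not None and tid in gene_map:
            gene = gene_map[tid]
        if gene is None:
            raise FormatError(f"transcript {tid!r}: no gene assignment")
        seq = str(rec.seq).upper()
        records.append(TranscriptRecord(tid, gene, seq))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id} gene={rec.gene_id}\n{rec.sequence}\n")


def read_gene_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column transcript→gene TSV (no header)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            tid, gene = parts
            if tid in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate transcript id {tid!r}")
            mapping[tid] = gene
    return mapping


# ---------------------------------------------------------------------------
# Probe table


def read_probe_tab(path: str | os.PathLike) -> list[ProbeTableRow]:
    """Read an Affymetrix-style tab-separated probe table.

    Validates the 25-mer constraint per row, (x, y) uniqueness across the
    design, and the PM/MM pairing rule: the two oligos of a pair differ at
    exactly the 13th base (1-based).
    """
    rows: list[ProbeTableRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != PROBE_TAB_COLUMNS:
            raise FormatError(
                f"{path}: header must be {PROBE_TAB_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                row = ProbeTableRow(
                    probeset_id=parts[0],
                    probe_id=parts[1],
                    x=int(parts[2]),
                    y=int(parts[3]),
                    interrogation_position=int(parts[4]),
                    sequence=parts[5],
                    role=parts[6],
                )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append(row)
    coords = [(r.x, r.y) for r in rows]
    if len(set(coords)) != len(coords):
        dupes = sorted({c for c in coords if coords.count(c) > 1})
        raise FormatError(f"{path}: duplicate grid coordinates {dupes[:5]}")
    _validate_pairs(rows, path)
    return rows


def _validate_pairs(rows: Sequence[ProbeTableRow], path) -> None:
    by_pair: dict[str, dict[str, ProbeTableRow]] = {}
    for row in rows:
        slot = by_pair.setdefault(row.probe_id, {})
        if row.role in slot:
            raise FormatError(f"{path}: probe pair {row.probe_id!r} has two {row.role} rows")
        slot[row.role] = row
    for pid, slot in by_pair.items():
        if "PM" in slot and "MM" in slot:
            pm, mm = slot["PM"].sequence, slot["MM"].sequence
            diff = [i for i in range(25) if pm[i] != mm[i]]
            if diff != [12]:
                raise FormatError(
                    f"{path}: pair {pid!r}: PM/MM must differ at exactly base 13, "
                    f"differ at {[i + 1 for i in diff]}"
                )


def write_probe_tab(rows: Iterable[ProbeTableRow], path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(PROBE_TAB_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.probeset_id}\t{r.probe_id}\t{r.x}\t{r.y}\t"
                f"{r.interrogation_position}\t{r.sequence}\t{r.role}\n"
            )


# ---------------------------------------------------------------------------
# ASCII CEL version 3


def read_cel_text(path: str | os.PathLike) -> IntensityMatrix:
    """Read one ASCII CEL version-3 file into a single-sample matrix.

    Only the ``MEAN`` column is kept.  Any header library name is
    ignored: intensity data is bound to a library explicitly at
    remap time, never via the file header.
    """
    try:
        with open(path, "r", encoding="ascii") as fh:
            text = fh.read()
    except UnicodeDecodeError as exc:
        raise FormatError(
            f"{path}: not ASCII text — binary CEL (XDA/Calvin) is not supported, "
            "convert to the version-3 text dialect first"
        ) from exc
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1]
            if name in sections:
                raise FormatError(f"{path}: duplicate section [{name}]")
            current = sections[name] = []
        elif current is not None:
            current.append(line)
        else:
            raise FormatError(f"{path}: data before first section")

    for required in ("CEL", "HEADER", "INTENSITY"):
        if required not in sections:
            raise FormatError(f"{path}: missing section [{required}]")

    def _kv(section: str) -> dict[str, str]:
        out = {}
        for line in sections[section]:
            if "=" in line:
                k, v = line.split("=", 1)
                out[k.strip()] = v.strip()
        return out

    cel = _kv("CEL")
    if cel.get("Version") != "3":
        raise FormatError(f"{path}: [CEL] Version must be 3, got {cel.get('Version')!r}")
    header = _kv("HEADER")
    try:
        cols = int(header["Cols"])
        rows = int(header["Rows"])
    except KeyError as exc:
        raise FormatError(f"{path}: [HEADER] missing Cols/Rows") from exc

    intensity_lines = sections["INTENSITY"]
    kv = _kv("INTENSITY")
    if "NumberCells" not in kv:
        raise FormatError(f"{path}: [INTENSITY] missing NumberCells")
    n_cells = int(kv["NumberCells"])
    if n_cells != rows * cols:
        raise FormatError(
            f"{path}: NumberCells={n_cells} but grid is {rows}x{cols}={rows * cols}"
        )
    data_lines = [ln for ln in intensity_lines if "=" not in ln]
    if len(data_lines) != n_cells:
        raise FormatError(
            f"{path}: NumberCells={n_cells} but {len(data_lines)} data lines present"
        )
    grid = np.full((rows, cols), np.nan)
    for ln in data_lines:
        parts = ln.split()
        if len(parts) != 5:
            raise FormatError(f"{path}: malformed intensity line {ln!r}")
        x, y = int(parts[0]), int(parts[1])
        mean = float(parts[2])
        if not (0 <= x < cols and 0 <= y < rows):
            raise FormatError(f"{path}: cell ({x},{y}) outside {rows}x{cols} grid")
        if not np.isnan(grid[y, x]):
            raise FormatError(f"{path}: duplicate cell ({x},{y})")
        if mean <= 0:
            raise FormatError(f"{path}: non-positive intensity at ({x},{y})")
        grid[y, x] = mean
    sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return IntensityMatrix([sample_id], grid[None, :, :])


def write_cel_text(grid: np.ndarray, path: str | os.PathLike) -> None:
    """Write a (rows, cols) intensity grid as ASCII CEL version 3."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D (rows, cols)")
    if not np.all(grid > 0):
        raise ValueError("intensities must be strictly positive")
    rows, cols = grid.shape
    with open(path, "w", newline="\n") as fh:
        fh.write("[CEL]\nVersion=3\n\n")
        fh.write(f"[HEADER]\nCols={cols}\nRows={rows}\n\n")
        fh.write(f"[INTENSITY]\nNumberCells={rows * cols}\n")
        fh.write("CellHeader=X\tY\tMEAN\tSTDV\tNPIXELS\n")
        for y in range(rows):
            for x in range(cols):
                fh.write(f"{x}\t{y}\t{float(grid[y, x])!r}\t0.0\t9\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read GMT gene sets: name, description, then member genes.

    Duplicate members within a set are deduplicated; empty sets and lines
    with fewer than three columns are format errors.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in parts[2:] if g}
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for name in sets:
            members = sorted(set(sets[name]))
            if not members:
                raise ValueError(f"set {name!r} is empty")
            fh.write(name + "\tna\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# Expression TSV


def write_expression_tsv(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write probe sets × samples expression to TSV, repr round-trip safe."""
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains NaN")
    with open(path, "w", newline="\n") as fh:
        fh.write("probeset_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for pid, row in zip(matrix.index, matrix.to_numpy()):
            fh.write(str(pid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if not header or header[0] != "probeset_id":
            raise FormatError(f"{path}: first column must be probeset_id")
        samples = header[1:]
        index, data = [], []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, header has {len(header)})"
                )
            index.append(parts[0])
            data.append([float(v) for v in parts[1:]])
    return pd.DataFrame(data, index=pd.Index(index, name="probeset_id"), columns=samples)
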