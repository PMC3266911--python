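"""Tab-separated / BED / JSON readers and writers for every pipeline format.

All tabular files are UTF-8 TSV with a single header row; genomic
intervals on disk are BED-style 0-based half-open.  Readers raise with the
offending line number on malformed input, and every writer/reader pair
round-trips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from oncoamp.cncall import CopyNumberProfile
from oncoamp.integrate import GeneModel

__all__ = [
    "read_probes",
    "write_probes",
    "read_matrix",
    "write_matrix",
    "read_genes_bed",
    "write_genes_bed",
    "write_segments",
    "read_segments",
    "write_json",
    "read_json",
    "file_checksum",
]


class ParseError(ValueError):
    """Malformed input file; message carries path and line number."""


def write_probes(probes: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    probes[["probe_id", "chrom", "pos"]].to_csv(path, sep="\t", index=False)
    return path


def read_probes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    probes = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = {"probe_id", "chrom", "pos"} - set(probes.columns)
    if missing:
        raise ParseError(f"{path}:1: probe table missing columns {sorted(missing)}")
    try:
        probes["pos"] = probes["pos"].astype(int)
    except (TypeError, ValueError):
        bad = pd.to_numeric(probes["pos"], errors="coerce").isna()
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ParseError(f"{path}:{line}: non-integer position {probes['pos'].iloc[line - 2]!r}")
    return probes


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "probe_id") -> Path:
    path = Path(path)
    out = matrix.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t")
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Numeric matrix with row ids in the first column."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        return raw.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(raw.columns):
            bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}:{i + 2}: non-numeric cell {raw[col].iloc[i]!r} "
                    f"(row {raw.index[i]!r}, column {col!r})"
                )
        raise ParseError(f"{path}: matrix contains non-numeric cells")


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")
    return path


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    path = Path(path)
    genes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates")
            try:
                genes.append(GeneModel(name=fields[3], chrom=fields[0], start=start, end=end))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}")
    return genes


_SEG_COLS = ["chrom", "start", "end", "sample", "cn", "b", "label"]


def write_segments(profiles: Sequence[CopyNumberProfile], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        (seg.chrom, seg.start_bp, seg.end_bp, prof.sample, seg.cn, seg.b, seg.label)
        for prof in profiles
        for seg in prof.segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)
    return path


def read_segments(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    segs = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "label": str})
    missing = set(_SEG_COLS) - set(segs.columns)
    if missing:
        raise ParseError(f"{path}:1: segment table missing columns {sorted(missing)}")
    return segs


def write_json(obj: object, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path: str | Path) -> object:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
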