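"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate conventions: everything in memory and in BED/PAF output is
0-based half-open; samtools-style per-base depth tables are 1-based
(converted on read, see :mod:`zparcall.depth`).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import pandas as pd

PathLike = Union[str, Path]

PAF_COLUMNS = [
    "query_name", "query_length", "query_start", "query_end", "strand",
    "target_name", "target_length", "target_start", "target_end",
    "n_match", "alignment_length", "mapq",
]

WINDOW_COLUMNS = ["scaffold", "start", "end", "mean_depth"]

FLOAT_FORMAT = "%.6f"


class FormatError(ValueError):
    """A file did not conform to the expected tabular dialect."""


def read_fai(path: PathLike) -> pd.Series:
    """Read a FAI-style length table (name<TAB>length[<TAB>...]).

    Returns a Series mapping scaffold name -> length. Extra columns (as in a
    real .fai produced by ``samtools faidx``) are ignored.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 tab-separated columns")
    lengths = pd.to_numeric(df[1], errors="coerce")
    if lengths.isna().any():
        bad = int(lengths.isna().idxmax()) + 1
        raise FormatError(f"{path}: non-numeric length on line {bad}")
    if (lengths <= 0).any():
        bad = int((lengths <= 0).idxmax()) + 1
        raise FormatError(f"{path}: non-positive length on line {bad}")
    if df[0].duplicated().any():
        dup = df[0][df[0].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate scaffold name {dup!r}")
    return pd.Series(lengths.astype("int64").values, index=df[0].values, name="length")


def write_fai(lengths: pd.Series, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in lengths.items():
            fh.write(f"{name}\t{int(length)}\n")


def read_paf(path: PathLike) -> pd.DataFrame:
    """Read the 12 mandatory PAF columns; optional SAM-like tags are ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {lineno}: expected >=12 columns, got {len(fields)}")
            try:
                rows.append((
                    fields[0], int(fields[1]), int(fields[2]), int(fields[3]),
                    fields[4],
                    fields[5], int(fields[6]), int(fields[7]), int(fields[8]),
                    int(fields[9]), int(fields[10]), int(fields[11]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if fields[4] not in "+-":
                raise FormatError(f"{path}: line {lineno}: strand must be + or -")
    df = pd.DataFrame(rows, columns=PAF_COLUMNS)
    bad = (df["query_end"] <= df["query_start"]) | (df["target_end"] <= df["target_start"])
    if bad.any():
        raise FormatError(f"{path}: line {int(bad.idxmax()) + 1}: empty or inverted interval")
    return df


def write_paf(records: pd.DataFrame, path: PathLike) -> None:
    records[PAF_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: PathLike) -> pd.DataFrame:
    """Read BED3+ into (chrom, start, end[, name[, score[, strand]]])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=names[: _ncols(path)], dtype={"chrom": str})
    if (df["end"] <= df["start"]).any():
        bad = int((df["end"] <= df["start"]).idxmax()) + 1
        raise FormatError(f"{path}: line {bad}: end <= start")
    return df


def _ncols(path: PathLike) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(len(line.rstrip("\n").split("\t")), 6)
    return 3


def write_bed(df: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    out = df[cols].copy()
    if "score" in out.columns:
        out["score"] = out["score"].map(lambda v: f"{v:.4f}" if isinstance(v, float) else v)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genes(path: PathLike) -> pd.DataFrame:
    """Read a gene annotation as (chrom, start, end, name), 0-based half-open.

    Dispatches on extension: ``.gff``/``.gff3`` are parsed as GFF3 gene
    features (1-based inclusive, converted; name from the ID attribute),
    anything else as BED.
    """
    if str(path).endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != 9:
                    raise FormatError(f"{path}: line {lineno}: expected 9 columns")
                if f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("ID") or attrs.get("Name") or f"gene_{lineno}"
                rows.append((f[0], int(f[3]) - 1, int(f[4]), name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return read_bed(path)


def read_window_table(path: PathLike) -> pd.DataFrame:
    """Read a window-depth table: scaffold, start, end, mean_depth
    [, normalized_depth][, partial]. Header line optional."""
    first = open(path).readline()
    has_header = first.startswith("scaffold\t")
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if not has_header:
        ncol = df.shape[1]
        names = WINDOW_COLUMNS + ["normalized_depth", "partial"]
        df.columns = names[:ncol]
    for col in ("start", "end"):
        df[col] = df[col].astype("int64")
    df["mean_depth"] = df["mean_depth"].astype(float)
    if "partial" in df.columns:
        df["partial"] = df["partial"].astype(bool)
    else:
        df["partial"] = False
    df["scaffold"] = df["scaffold"].astype(str)
    if (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: window with end <= start")
    if (df["mean_depth"] < 0).any():
        raise FormatError(f"{path}: negative mean depth")
    return df


def write_window_table(df: pd.DataFrame, path: PathLike) -> None:
    cols = ["scaffold", "start", "end", "mean_depth"]
    for extra in ("normalized_depth", "partial"):
        if extra in df.columns:
            cols.append(extra)
    out = df[cols].copy()
    out["mean_depth"] = out["mean_depth"].map(lambda v: FLOAT_FORMAT % v)
    if "normalized_depth" in out.columns:
        out["normalized_depth"] = out["normalized_depth"].map(lambda v: FLOAT_FORMAT % v)
    if "partial" in out.columns:
        out["partial"] = out["partial"].astype(int)
    buf = _io.StringIO()
    out.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_config(path: PathLike) -> dict:
    """Flat ``key = value`` configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {lineno}: expected key = value")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
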