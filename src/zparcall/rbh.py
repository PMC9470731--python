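"""Reciprocal-best-hit (RBH) one-to-one orthology from tabular protein hits.

Consumes 12-column BLAST-tabular files (outfmt 6 dialect: qseqid sseqid
pident length mismatch gapopen qstart qend sstart send evalue bitscore;
extra columns tolerated). Per direction, each query keeps its best subject
by bitscore (ties: higher percent identity, then lexicographically smallest
subject id); a pair is an ortholog iff it is mutual. Pairwise maps against a
common reference gene set are merged into a one-to-one table, with rows
present in every species flagged complete.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

HIT_COLUMNS = ["query", "subject", "identity", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "e_value", "bitscore"]


class RBHError(ValueError):
    pass


def read_hits(path, e_value_cutoff: float = 1e-5) -> pd.DataFrame:
    """Read tabular hits, dropping rows with e-value above the cutoff.

    The number of dropped rows is recorded in ``df.attrs['n_dropped']``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise RBHError(f"{path}: line {lineno}: expected >=12 columns, got {len(f)}")
            try:
                rows.append((f[0], f[1], float(f[2]), int(f[3]), int(f[4]),
                             int(f[5]), int(f[6]), int(f[7]), int(f[8]),
                             int(f[9]), float(f[10]), float(f[11])))
            except ValueError as exc:
                raise RBHError(f"{path}: line {lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if (df["e_value"] < 0).any():
        raise RBHError(f"{path}: negative e-value")
    if ((df["identity"] < 0) | (df["identity"] > 100)).any():
        raise RBHError(f"{path}: identity outside [0, 100]")
    keep = df["e_value"] <= e_value_cutoff
    out = df[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


def best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: highest bitscore, ties by higher identity,
    then lexicographically smallest subject id. Self-hits are discarded."""
    df = hits[hits["query"] != hits["subject"]]
    if len(df) == 0:
        return {}
    df = df.sort_values(["query", "bitscore", "identity", "subject"],
                        ascending=[True, False, False, True], kind="stable")
    top = df.drop_duplicates("query", keep="first")
    return dict(zip(top["query"], top["subject"]))


def reciprocal_best(map_ab: Mapping[str, str],
                    map_ba: Mapping[str, str]) -> list[tuple[str, str]]:
    """Pairs (a, b) with map_ab[a] == b and map_ba[b] == a, sorted by a."""
    pairs = [(a, b) for a, b in map_ab.items() if map_ba.get(b) == a]
    return sorted(pairs)


def merge_orthologs(pairwise: Mapping[str, Iterable[tuple[str, str]]]
                    ) -> pd.DataFrame:
    """Merge reference-vs-species RBH pairs into a one-to-one ortholog table.

    ``pairwise`` maps species name -> iterable of (reference_gene,
    species_gene) pairs. One row per reference gene; the ``complete`` flag
    marks genes recovered in every species. A species gene assigned to two
    reference genes violates the RBH one-to-one property and is an error.
    """
    species = sorted(pairwise)
    columns: dict[str, dict[str, str]] = {}
    for sp in species:
        colmap: dict[str, str] = {}
        seen: dict[str, str] = {}
        for ref_gene, sp_gene in pairwise[sp]:
            if ref_gene in colmap:
                raise RBHError(
                    f"{sp}: reference gene {ref_gene!r} assigned twice")
            if sp_gene in seen:
                raise RBHError(
                    f"{sp}: gene {sp_gene!r} assigned to both "
                    f"{seen[sp_gene]!r} and {ref_gene!r} (not one-to-one)")
            colmap[ref_gene] = sp_gene
            seen[sp_gene] = ref_gene
        columns[sp] = colmap
    ref_genes = sorted({g for colmap in columns.values() for g in colmap})
    table = pd.DataFrame(index=pd.Index(ref_genes, name="reference_gene"))
    for sp in species:
        table[sp] = [columns[sp].get(g) for g in ref_genes]
    table["complete"] = table[species].notna().all(axis=1)
    return table.reset_index()
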