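"""Reference-guided pseudo-Z construction and coordinate projection.

Z-candidate scaffolds are ordered by where they anchor on the reference Z
(median of alignment-block midpoints), oriented by majority strand, and laid
end-to-end with fixed gaps into a single pseudo-chromosome — a lightweight
re-implementation of reference-guided scaffolding sufficient for depth-track
visualization and interval bookkeeping. Outputs: AGP v2.1, a binned
PAR/DR/GAP track, and exact (bijective) projection of scaffold-local
intervals into pseudo-chromosome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import math

import numpy as np
import pandas as pd


class PseudoZError(ValueError):
    pass


@dataclass(frozen=True)
class ScaffoldPlacement:
    scaffold: str
    offset: int          # 0-based pseudo-chromosome start
    orientation: str     # + / -
    anchor_position: float  # NaN for unplaceable scaffolds
    length: int
    placed: bool = True  # False: no alignment anchor, appended at the end


@dataclass(frozen=True)
class TrackParams:
    resolution: int = 100_000
    window_size: int = 5_000

    def __post_init__(self):
        if self.resolution <= 0 or self.window_size <= 0:
            raise PseudoZError("resolution and window_size must be > 0")
        if self.resolution % self.window_size != 0:
            raise PseudoZError(
                f"track resolution {self.resolution} must be a multiple of the "
                f"depth window size {self.window_size}")


def anchor_scaffolds(summaries: pd.DataFrame,
                     gap_size: int = 100) -> list[ScaffoldPlacement]:
    """Order and orient scaffolds along the reference Z.

    Sort key: anchor position (median block midpoint on the reference), ties
    broken by scaffold name. Scaffolds with no alignment blocks cannot be
    anchored; they are appended after the placed ones, flagged
    ``placed=False``, so total Z-linked sequence is preserved.
    """
    anchored = summaries[summaries["n_blocks"] > 0].sort_values(
        ["anchor_position", "scaffold"], kind="stable")
    unanchored = summaries[summaries["n_blocks"] == 0].sort_values("scaffold")
    placements = []
    offset = 0
    for part, placed in ((anchored, True), (unanchored, False)):
        for rec in part.itertuples(index=False):
            if placements:
                offset += gap_size
            placements.append(ScaffoldPlacement(
                scaffold=rec.scaffold, offset=offset,
                orientation=rec.majority_strand if placed else "+",
                anchor_position=float(rec.anchor_position) if placed else math.nan,
                length=int(rec.length), placed=placed))
            offset += int(rec.length)
    return placements


def total_length(placements: Sequence[ScaffoldPlacement]) -> int:
    if not placements:
        return 0
    last = placements[-1]
    return last.offset + last.length


def placement_table(placements: Sequence[ScaffoldPlacement]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.scaffold, p.offset, p.orientation, p.anchor_position, p.length,
          p.placed) for p in placements],
        columns=["scaffold", "offset", "orientation", "anchor_position",
                 "length", "placed"])


# --- coordinate projection ---------------------------------------------------

def project_interval(placement: ScaffoldPlacement, start: int,
                     end: int) -> tuple[int, int]:
    """Map a scaffold-local half-open interval into pseudo-Z coordinates.

    A ``-`` orientation reflects coordinates within the scaffold
    (end' = L - start), so base adjacency is preserved.
    """
    if not 0 <= start < end <= placement.length:
        raise PseudoZError(
            f"interval [{start}, {end}) outside scaffold {placement.scaffold} "
            f"of length {placement.length}")
    if placement.orientation == "+":
        return placement.offset + start, placement.offset + end
    return (placement.offset + placement.length - end,
            placement.offset + placement.length - start)


def invert_interval(placement: ScaffoldPlacement, pstart: int,
                    pend: int) -> tuple[int, int]:
    """Inverse of :func:`project_interval` for intervals inside one scaffold."""
    s, e = pstart - placement.offset, pend - placement.offset
    if not 0 <= s < e <= placement.length:
        raise PseudoZError("interval outside placement")
    if placement.orientation == "+":
        return s, e
    return placement.length - e, placement.length - s


def project_windows(placements: Sequence[ScaffoldPlacement],
                    windows: pd.DataFrame) -> pd.DataFrame:
    """Attach pseudo-chromosome coordinates to windows of placed scaffolds,
    returned sorted along the pseudo-chromosome."""
    by_name = {p.scaffold: p for p in placements}
    sub = windows[windows["scaffold"].isin(by_name)].copy()
    ps, pe = [], []
    for rec in sub.itertuples(index=False):
        a, b = project_interval(by_name[rec.scaffold], rec.start, rec.end)
        ps.append(a)
        pe.append(b)
    sub["pseudo_start"] = ps
    sub["pseudo_end"] = pe
    return sub.sort_values("pseudo_start", kind="stable", ignore_index=True)


def locate_marker_gene(genes: pd.DataFrame,
                       placements: Sequence[ScaffoldPlacement],
                       gene_name: str) -> tuple[int, int]:
    """Pseudo-chromosome interval of a named gene (e.g. a DMRT1 locus used
    as a positional marker). The gene table is scaffold-local BED-like with
    columns (chrom, start, end, name)."""
    hit = genes[genes["name"] == gene_name]
    if len(hit) == 0:
        raise PseudoZError(f"gene {gene_name!r} not found in annotation")
    rec = hit.iloc[0]
    by_name = {p.scaffold: p for p in placements}
    if rec["chrom"] not in by_name:
        raise PseudoZError(
            f"gene {gene_name!r} lies on scaffold {rec['chrom']!r}, which is "
            "not placed on the pseudo-chromosome")
    return project_interval(by_name[rec["chrom"]], int(rec["start"]), int(rec["end"]))


# --- AGP ---------------------------------------------------------------------

AGP_GAP_TYPE = "scaffold"
AGP_EVIDENCE = "align_genus"


def emit_agp(placements: Sequence[ScaffoldPlacement], gap_size: int = 100,
             object_name: str = "pseudoZ") -> str:
    """Render placements as AGP v2.1 (1-based inclusive coordinates),
    alternating W (component) and N (gap) lines."""
    lines = ["##agp-version\t2.1"]
    part = 0
    pos = 0  # 0-based cursor
    for i, p in enumerate(placements):
        if i > 0:
            part += 1
            lines.append("\t".join([
                object_name, str(pos + 1), str(pos + gap_size), str(part),
                "N", str(gap_size), AGP_GAP_TYPE, "yes", AGP_EVIDENCE]))
            pos += gap_size
        if p.offset != pos:
            raise PseudoZError(
                f"placement offsets inconsistent with gap size {gap_size}: "
                f"{p.scaffold} at {p.offset}, expected {pos}")
        part += 1
        lines.append("\t".join([
            object_name, str(pos + 1), str(pos + p.length), str(part),
            "W", p.scaffold, "1", str(p.length), p.orientation]))
        pos += p.length
    return "\n".join(lines) + "\n"


def read_agp(text: str) -> list[ScaffoldPlacement]:
    """Parse component lines of an AGP back into placements (anchors and the
    placed flag are not stored in AGP and come back as NaN/True)."""
    placements = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise PseudoZError(f"AGP line has {len(f)} columns, expected 9")
        if f[4] == "N" or f[4] == "U":
            continue
        obj_beg, obj_end = int(f[1]), int(f[2])
        comp_beg, comp_end = int(f[6]), int(f[7])
        if comp_beg != 1 or comp_end != obj_end - obj_beg + 1:
            raise PseudoZError(f"partial component placements unsupported: {f[5]}")
        placements.append(ScaffoldPlacement(
            scaffold=f[5], offset=obj_beg - 1, orientation=f[8],
            anchor_position=math.nan, length=comp_end, placed=True))
    return placements


# --- binned track ------------------------------------------------------------

def project_track(placements: Sequence[ScaffoldPlacement],
                  proj_windows: pd.DataFrame, segments: pd.DataFrame,
                  params: TrackParams = TrackParams(),
                  object_name: str = "pseudoZ") -> pd.DataFrame:
    """Binned PAR/DR/GAP depth track over the pseudo-chromosome.

    Each bin of ``params.resolution`` bases reports the coverage-weighted
    mean normalized depth of the windows overlapping it; bins with no depth
    data (inter-scaffold gaps, unsequenced stretches) are labeled GAP, the
    rest PAR or DR by majority overlap with the called segments.
    """
    length = total_length(placements)
    n_bins = (length + params.resolution - 1) // params.resolution
    depth_sum = np.zeros(n_bins)
    cover = np.zeros(n_bins)
    res = params.resolution
    for rec in proj_windows.itertuples(index=False):
        b0 = rec.pseudo_start // res
        b1 = (rec.pseudo_end - 1) // res
        for b in range(b0, b1 + 1):
            ov = min(rec.pseudo_end, (b + 1) * res) - max(rec.pseudo_start, b * res)
            depth_sum[b] += rec.normalized_depth * ov
            cover[b] += ov
    par_ov = np.zeros(n_bins)
    seg_ov = np.zeros(n_bins)
    for rec in segments.itertuples(index=False):
        b0 = rec.start // res
        b1 = (rec.end - 1) // res
        for b in range(b0, b1 + 1):
            ov = min(rec.end, (b + 1) * res) - max(rec.start, b * res)
            seg_ov[b] += ov
            if rec.label == "PAR":
                par_ov[b] += ov
    rows = []
    for b in range(n_bins):
        start, end = b * res, min((b + 1) * res, length)
        if cover[b] == 0:
            label, mean = "GAP", np.nan
        else:
            mean = depth_sum[b] / cover[b]
            label = "PAR" if par_ov[b] * 2 > seg_ov[b] else "DR"
        rows.append((object_name, start, end, label, mean))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
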