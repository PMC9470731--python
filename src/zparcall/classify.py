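"""Z-linkage classification, sex inference, PAR calling and reversal detection.

The logic follows the standard coverage heuristics for ZW genomes assembled
from a single sequenced individual:

* a scaffold is a Z candidate when more than half of its bases align to a
  reference Z chromosome (merged union of alignment blocks, strict >0.5);
* the sample is female when the modal normalized depth of Z-candidate
  windows sits near 0.5 (one Z copy) while the rest of the genome peaks at
  1.0; a male shows both peaks at ~1.0;
* in a female, Z regions whose normalized depth exceeds 0.7 (strict) are
  pseudoautosomal (two copies), the remainder is the differentiated region;
* a PAR far exceeding the ~600 Kb conserved avian PAR flags a candidate
  DR-to-PAR/autosome reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import depth as zdepth

Z_CANDIDATE = "Z_CANDIDATE"
NOT_Z = "NOT_Z"


class ClassifyError(ValueError):
    pass


# --- alignment summaries -----------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals by sort-and-sweep."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def summarize_alignment_rates(paf: pd.DataFrame, lengths: pd.Series,
                              reference_z_name: str) -> pd.DataFrame:
    """Per-scaffold aligned fraction against the reference Z.

    Query intervals of all blocks hitting ``reference_z_name`` are merged
    (union) before computing the aligned-base count, so overlapping or
    duplicated blocks never inflate the rate. The majority strand is taken by
    aligned-base weight (ties -> ``+``) and the anchor is the median of block
    midpoints on the reference, used downstream to order scaffolds.
    """
    unknown = set(paf["query_name"]) - set(lengths.index)
    if unknown:
        raise ClassifyError(
            f"scaffolds in PAF absent from length table: {sorted(unknown)[:5]}")
    onz = paf[paf["target_name"] == reference_z_name]
    rows = []
    grouped = dict(iter(onz.groupby("query_name", sort=False)))
    for scaffold, length in lengths.items():
        length = int(length)
        g = grouped.get(scaffold)
        if g is None or len(g) == 0:
            rows.append((scaffold, length, 0, 0.0, "+", np.nan, 0))
            continue
        aligned = union_length(zip(g["query_start"], g["query_end"]))
        block_lens = (g["query_end"] - g["query_start"]).to_numpy()
        minus = block_lens[(g["strand"] == "-").to_numpy()].sum()
        strand = "-" if minus > block_lens.sum() - minus else "+"
        midpoints = (g["target_start"] + g["target_end"]).to_numpy() / 2.0
        anchor = float(np.median(midpoints))
        rows.append((scaffold, length, aligned, aligned / length, strand,
                     anchor, len(g)))
    return pd.DataFrame(rows, columns=[
        "scaffold", "length", "aligned_bases", "alignment_rate",
        "majority_strand", "anchor_position", "n_blocks"])


def classify_z_scaffolds(summaries: pd.DataFrame,
                         rate_threshold: float = 0.5) -> pd.DataFrame:
    """Call Z candidacy: alignment rate strictly above the threshold."""
    if len(summaries) == 0:
        raise ClassifyError("no scaffolds to classify")
    out = summaries.copy()
    out["call"] = np.where(out["alignment_rate"] > rate_threshold,
                           Z_CANDIDATE, NOT_Z)
    out.attrs["rate_threshold"] = rate_threshold
    return out


# --- sex inference -----------------------------------------------------------

@dataclass(frozen=True)
class SexCallParams:
    female_band: tuple[float, float] = (0.3, 0.7)
    male_min: float = 0.85
    bin_width: float = 0.02
    min_windows: int = 100


@dataclass(frozen=True)
class SexCall:
    call: str  # MALE / FEMALE / UNDETERMINED
    z_modal_depth: float
    not_z_modal_depth: Optional[float]
    params: SexCallParams = field(default_factory=SexCallParams)

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "z_modal_depth": self.z_modal_depth,
            "not_z_modal_depth": self.not_z_modal_depth,
            "female_band": list(self.params.female_band),
            "male_min": self.params.male_min,
            "bin_width": self.params.bin_width,
        }


def infer_sex(windows: pd.DataFrame, zcalls: pd.DataFrame,
              params: SexCallParams = SexCallParams()) -> SexCall:
    """Infer sample sex from the modal normalized depth of Z-candidate windows.

    A female (ZW) carries one copy of the differentiated Z, so the Z-window
    mode falls near 0.5; a male (ZZ) matches the autosomal mode at 1.0.
    """
    if "normalized_depth" not in windows.columns:
        raise ClassifyError("windows must carry normalized_depth (run normalization first)")
    z_names = set(zcalls.loc[zcalls["call"] == Z_CANDIDATE, "scaffold"])
    if not z_names:
        raise ClassifyError("no Z-candidate scaffolds; sex cannot be assessed")
    z_windows = windows[windows["scaffold"].isin(z_names)]
    nz_windows = windows[~windows["scaffold"].isin(z_names)]
    z_peak = zdepth.estimate_depth_peak(
        z_windows, bin_width=params.bin_width, column="normalized_depth",
        min_full_windows=params.min_windows)
    nz_mode: Optional[float] = None
    try:
        nz_mode = zdepth.estimate_depth_peak(
            nz_windows, bin_width=params.bin_width, column="normalized_depth",
            min_full_windows=params.min_windows).peak_depth
    except zdepth.DepthProfileError:
        pass
    lo, hi = params.female_band
    mode = z_peak.peak_depth
    if lo <= mode <= hi:
        call = "FEMALE"
    elif mode >= params.male_min:
        call = "MALE"
    else:
        call = "UNDETERMINED"
    return SexCall(call=call, z_modal_depth=mode, not_z_modal_depth=nz_mode,
                   params=params)


# --- PAR calling -------------------------------------------------------------

def call_par_scaffolds(windows: pd.DataFrame, zcalls: pd.DataFrame,
                       sexcall: SexCall,
                       depth_threshold: float = 0.7) -> pd.DataFrame:
    """Scaffold-level PAR candidacy for a female sample.

    The per-scaffold statistic is the median normalized depth over full
    windows (robust to repeat-driven spikes); a Z candidate is a PAR
    candidate iff the median is strictly above the threshold. Only the
    heterogametic (female) sample shows the PAR/DR depth contrast.
    """
    if sexcall.call != "FEMALE":
        raise ClassifyError(
            f"PAR calling requires a FEMALE sample (heterogametic sex); got {sexcall.call}")
    z_names = set(zcalls.loc[zcalls["call"] == Z_CANDIDATE, "scaffold"])
    full = windows[~windows["partial"]] if "partial" in windows.columns else windows
    med = full.groupby("scaffold")["normalized_depth"].median()
    rows = []
    for scaffold in zcalls.loc[zcalls["call"] == Z_CANDIDATE, "scaffold"]:
        m = float(med.get(scaffold, np.nan))
        rows.append((scaffold, m, bool(m > depth_threshold)))
    out = pd.DataFrame(rows, columns=["scaffold", "median_norm_depth", "par_candidate"])
    out.attrs["depth_threshold"] = depth_threshold
    return out


# --- window-level segmentation ----------------------------------------------

def segment_depth_track(windows: pd.DataFrame, depth_threshold: float = 0.7,
                        min_run: int = 3, max_gap: int = 2) -> pd.DataFrame:
    """Segment a pseudo-chromosome depth track into PAR and DR intervals.

    ``windows`` must be ordered along the pseudo-chromosome and carry
    ``pseudo_start``/``pseudo_end`` plus ``normalized_depth``. Maximal runs
    of windows strictly above the threshold are labeled PAR, with up to
    ``max_gap`` consecutive sub-threshold windows absorbed inside a run and
    runs shorter than ``min_run`` windows discarded (single-window noise
    suppression). The remainder of the covered extent is DR; segments tile
    [first window start, last window end).
    """
    required = {"pseudo_start", "pseudo_end", "normalized_depth"}
    missing = required - set(windows.columns)
    if missing:
        raise ClassifyError(f"windows lack columns {sorted(missing)}")
    if len(windows) == 0:
        return pd.DataFrame(columns=["start", "end", "label", "mean_norm_depth",
                                     "n_windows"])
    starts = windows["pseudo_start"].to_numpy()
    if np.any(np.diff(starts) < 0):
        raise ClassifyError("windows are not ordered along the pseudo-chromosome")
    above = (windows["normalized_depth"].to_numpy() > depth_threshold)
    idx = np.flatnonzero(above)
    runs: list[tuple[int, int]] = []  # inclusive index ranges of PAR runs
    if len(idx):
        run_start = prev = idx[0]
        n_above = 1
        for i in idx[1:]:
            if i - prev - 1 <= max_gap:
                prev = i
                n_above += 1
            else:
                if n_above >= min_run:
                    runs.append((run_start, prev))
                run_start = prev = i
                n_above = 1
        if n_above >= min_run:
            runs.append((run_start, prev))
    ends = windows["pseudo_end"].to_numpy()
    norm = windows["normalized_depth"].to_numpy()
    extent = (int(starts[0]), int(ends[-1]))
    segments: list[tuple[int, int, str]] = []
    cursor = extent[0]
    for a, b in runs:
        if starts[a] > cursor:
            segments.append((cursor, int(starts[a]), "DR"))
        segments.append((int(starts[a]), int(ends[b]), "PAR"))
        cursor = int(ends[b])
    if cursor < extent[1]:
        segments.append((cursor, extent[1], "DR"))
    rows = []
    for s, e, label in segments:
        inside = (starts >= s) & (ends <= e)
        rows.append((s, e, label,
                     float(norm[inside].mean()) if inside.any() else np.nan,
                     int(inside.sum())))
    out = pd.DataFrame(rows, columns=["start", "end", "label",
                                      "mean_norm_depth", "n_windows"])
    out.attrs.update(depth_threshold=depth_threshold, min_run=min_run,
                     max_gap=max_gap)
    return out


# --- reversal detection ------------------------------------------------------

@dataclass(frozen=True)
class ReversalFlag:
    flagged: bool
    total_par_length: int
    expected_par_length: int
    reversal_min_length: int
    ancestral_dr_overlap: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "flagged": self.flagged,
            "total_par_length": self.total_par_length,
            "expected_par_length": self.expected_par_length,
            "reversal_min_length": self.reversal_min_length,
            "ancestral_dr_overlap": self.ancestral_dr_overlap,
        }


def detect_reversal(segments: pd.DataFrame, expected_par_length: int,
                    reversal_min_length: int = 5_000_000,
                    ancestral_dr: Optional[Sequence[tuple[int, int]]] = None
                    ) -> ReversalFlag:
    """Flag a candidate DR-to-PAR/autosome reversal.

    Raised iff the total called PAR length strictly exceeds
    ``reversal_min_length`` — an order of magnitude above the conserved
    ~600 Kb avian PAR. When ancestral DR intervals (pseudo-chromosome
    coordinates) are supplied, the PAR overlap with them is reported, which
    localizes the reverted block.
    """
    par = segments[segments["label"] == "PAR"]
    total = int((par["end"] - par["start"]).sum())
    overlap = None
    if ancestral_dr is not None:
        overlap = 0
        for _, seg in par.iterrows():
            for s, e in ancestral_dr:
                overlap += max(0, min(seg["end"], e) - max(seg["start"], s))
        overlap = int(overlap)
    return ReversalFlag(flagged=bool(total > reversal_min_length),
                        total_par_length=total,
                        expected_par_length=int(expected_par_length),
                        reversal_min_length=int(reversal_min_length),
                        ancestral_dr_overlap=overlap)


# --- gene counting -----------------------------------------------------------

def count_genes_in_segments(segments: pd.DataFrame,
                            genes: pd.DataFrame) -> pd.DataFrame:
    """Fill ``gene_count`` per segment: each gene is counted once, in the
    segment holding the largest part of its span (ties -> leftmost segment;
    genes with no overlap are not counted)."""
    out = segments.copy().reset_index(drop=True)
    counts = np.zeros(len(out), dtype=int)
    seg_starts = out["start"].to_numpy()
    seg_ends = out["end"].to_numpy()
    for rec in genes.itertuples(index=False):
        lo = int(np.searchsorted(seg_ends, rec.start, side="right"))
        hi = int(np.searchsorted(seg_starts, rec.end, side="left"))
        best, best_ov = -1, 0
        for j in range(lo, hi):
            ov = min(rec.end, seg_ends[j]) - max(rec.start, seg_starts[j])
            if ov > best_ov:
                best, best_ov = j, ov
        if best >= 0:
            counts[best] += 1
    out["gene_count"] = counts
    return out
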