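"""End-to-end orchestration: simulate -> depth -> classify -> build-z -> report.

The pipeline consumes either a packaged simulation preset (writing the
synthetic inputs to disk and reading them back, so every stage exercises the
file interfaces) or user-supplied files in the same formats. All thresholds
and the seed are echoed into the summary report for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import classify as zclassify
from . import depth as zdepth
from . import io as zio
from . import pseudoz
from . import synth

log = logging.getLogger("zparcall")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "zparcall_out"
    preset: Optional[str] = "typical"   # None: classify user-supplied files
    sex: Optional[str] = None           # override preset sex (simulation only)
    seed: int = 0
    # input paths (used when preset is None)
    windows_path: Optional[str] = None
    lengths_path: Optional[str] = None
    paf_path: Optional[str] = None
    genes_path: Optional[str] = None
    reference_z_name: str = "ref_chrZ"
    # thresholds (defaults match the published procedure)
    window_size: int = 5_000
    rate_threshold: float = 0.5
    par_depth_threshold: float = 0.7
    min_run: int = 3
    max_gap: int = 2
    reversal_min_length: int = 5_000_000
    expected_par_length: Optional[int] = None  # default: preset's ancestral PAR
    gap_size: int = 100
    track_resolution: int = 100_000

    def thresholds(self) -> dict:
        return {
            "window_size": self.window_size,
            "rate_threshold": self.rate_threshold,
            "par_depth_threshold": self.par_depth_threshold,
            "min_run": self.min_run,
            "max_gap": self.max_gap,
            "reversal_min_length": self.reversal_min_length,
            "gap_size": self.gap_size,
            "track_resolution": self.track_resolution,
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    calls: pd.DataFrame
    sexcall: zclassify.SexCall
    par_scaffolds: pd.DataFrame
    segments: pd.DataFrame
    reversal: zclassify.ReversalFlag
    placements: list
    track: pd.DataFrame
    summary: dict
    sample: Optional[synth.SimulatedSample] = None


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %-10s %6.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("simulate")
def _simulate(cfg: PipelineConfig, out: Path):
    sim_cfg = synth.manakin_preset(cfg.preset, seed=cfg.seed)
    if cfg.sex is not None:
        sim_cfg = dataclasses.replace(sim_cfg, sex=cfg.sex)
    sample = synth.simulate_sample(sim_cfg)
    synth.write_sample(sample, out)
    return sample


@_stage("depth")
def _normalize(windows: pd.DataFrame):
    return zdepth.profile_windows(windows)


@_stage("classify")
def _classify(cfg: PipelineConfig, windows, paf, lengths):
    summaries = zclassify.summarize_alignment_rates(paf, lengths,
                                                    cfg.reference_z_name)
    zcalls = zclassify.classify_z_scaffolds(summaries, cfg.rate_threshold)
    sexcall = zclassify.infer_sex(windows, zcalls)
    return summaries, zcalls, sexcall


@_stage("build-z")
def _build(cfg: PipelineConfig, zcalls, windows):
    z_sum = zcalls[zcalls["call"] == zclassify.Z_CANDIDATE]
    placements = pseudoz.anchor_scaffolds(z_sum, gap_size=cfg.gap_size)
    proj = pseudoz.project_windows(placements, windows)
    return placements, proj


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write all result files under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sample = None
    if cfg.preset is not None:
        sample = _simulate(cfg, out)
        windows = zio.read_window_table(out / "windows.tsv")
        lengths = zio.read_fai(out / "scaffolds.fai")
        paf = zio.read_paf(out / "alignments.paf")
        genes = zio.read_bed(out / "genes.bed")
        expected_par = (cfg.expected_par_length
                        if cfg.expected_par_length is not None
                        else sample.config.ancestral_par_length)
    else:
        for name, p in (("windows", cfg.windows_path), ("lengths", cfg.lengths_path),
                        ("alignments", cfg.paf_path)):
            if p is None:
                raise PipelineError("input", f"missing required {name} path")
        windows = zio.read_window_table(cfg.windows_path)
        lengths = zio.read_fai(cfg.lengths_path)
        paf = zio.read_paf(cfg.paf_path)
        genes = zio.read_genes(cfg.genes_path) if cfg.genes_path else pd.DataFrame(
            columns=["chrom", "start", "end", "name"])
        expected_par = cfg.expected_par_length or 600_000

    windows, peak = _normalize(windows)
    summaries, zcalls, sexcall = _classify(cfg, windows, paf, lengths)
    placements, proj = _build(cfg, zcalls, windows)

    par_scaffolds = pd.DataFrame(columns=["scaffold", "median_norm_depth",
                                          "par_candidate"])
    segments = pd.DataFrame(columns=["start", "end", "label", "mean_norm_depth",
                                     "n_windows", "gene_count"])
    reversal = zclassify.ReversalFlag(False, 0, int(expected_par),
                                      cfg.reversal_min_length)
    if sexcall.call == "FEMALE":
        par_scaffolds = zclassify.call_par_scaffolds(
            windows, zcalls, sexcall, cfg.par_depth_threshold)
        segments = zclassify.segment_depth_track(
            proj, cfg.par_depth_threshold, cfg.min_run, cfg.max_gap)
        reversal = zclassify.detect_reversal(
            segments, expected_par, cfg.reversal_min_length)

    # genes -> pseudo-Z coordinates -> per-segment counts
    by_name = {p.scaffold: p for p in placements}
    gene_rows = []
    for rec in genes.itertuples(index=False):
        if rec.chrom in by_name:
            s, e = pseudoz.project_interval(by_name[rec.chrom],
                                            int(rec.start), int(rec.end))
            gene_rows.append((rec.chrom, s, e, rec.name))
    genes_pseudo = pd.DataFrame(gene_rows,
                                columns=["scaffold", "start", "end", "name"])
    if len(segments):
        segments = zclassify.count_genes_in_segments(segments, genes_pseudo)

    track = pseudoz.project_track(
        placements, proj, segments,
        pseudoz.TrackParams(cfg.track_resolution, cfg.window_size))

    z_mask = zcalls["call"] == zclassify.Z_CANDIDATE
    z_names = set(zcalls.loc[z_mask, "scaffold"])
    par_seg = segments[segments["label"] == "PAR"] if len(segments) else segments
    summary = {
        "tool": "zparcall",
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "thresholds": cfg.thresholds(),
        "depth_peak": peak.peak_depth,
        "sex": sexcall.to_dict(),
        "z_length": int(zcalls.loc[z_mask, "length"].sum()),
        "z_scaffolds": int(z_mask.sum()),
        "z_genes": int(genes["chrom"].isin(z_names).sum()) if len(genes) else 0,
        "par_length": int((par_seg["end"] - par_seg["start"]).sum()) if len(par_seg) else 0,
        "par_genes": int(par_seg["gene_count"].sum()) if "gene_count" in par_seg.columns and len(par_seg) else 0,
        "reversal": reversal.to_dict(),
    }

    _write_outputs(out, cfg, zcalls, par_scaffolds, sexcall, segments,
                   reversal, placements, track, summary)
    return PipelineResult(cfg, zcalls, sexcall, par_scaffolds, segments,
                          reversal, placements, track, summary, sample)


def _write_outputs(out: Path, cfg, zcalls, par_scaffolds, sexcall, segments,
                   reversal, placements, track, summary) -> None:
    calls = zcalls.merge(par_scaffolds, on="scaffold", how="left")
    calls["alignment_rate"] = calls["alignment_rate"].map(lambda v: f"{v:.6f}")
    calls[["scaffold", "length", "alignment_rate", "call", "median_norm_depth",
           "par_candidate"]].to_csv(out / "scaffold_calls.tsv", sep="\t",
                                    index=False, float_format="%.6f")
    (out / "sex_call.json").write_text(
        json.dumps(sexcall.to_dict(), indent=2, sort_keys=True) + "\n")
    if len(segments):
        seg_bed = segments.rename(columns={"label": "name"}).assign(chrom="pseudoZ")
        zio.write_bed(seg_bed[["chrom", "start", "end", "name"]],
                      out / "par_segments.bed")
    else:
        (out / "par_segments.bed").write_text("")
    (out / "reversal.json").write_text(
        json.dumps(reversal.to_dict(), indent=2, sort_keys=True) + "\n")
    (out / "pseudoZ.agp").write_text(
        pseudoz.emit_agp(placements, gap_size=cfg.gap_size))
    pseudoz.placement_table(placements).to_csv(
        out / "placements.tsv", sep="\t", index=False, float_format="%.1f")
    zio.write_bed(track, out / "track.bed")
    write_report(summary, out / "summary.json")


def write_report(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True,
                                     default=str) + "\n")
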