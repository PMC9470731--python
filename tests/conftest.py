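import dataclasses
import time

import pandas as pd
import pytest

from zparcall import classify as zclassify
from zparcall import depth as zdepth
from zparcall import pseudoz, synth


def small_karyotype() -> synth.KaryotypeSpec:
    """A desk-size genome: 3 Mb autosome, 2.4 Mb Z (600 Kb PAR), 0.5 Mb W."""
    return synth.KaryotypeSpec((
        synth.uniform_chromosome("chr1", 3_000_000),
        synth.ChromosomeSpec("chrZ", 2_400_000, (
            synth.Region(synth.Z_PAR, 0, 600_000),
            synth.Region(synth.Z_DR, 600_000, 2_400_000))),
        synth.uniform_chromosome("chrW", 500_000, synth.W),
    ))


@pytest.fixture
def small_config() -> synth.SimulationConfig:
    return synth.SimulationConfig(
        karyotype=small_karyotype(),
        depth_model=synth.DepthModel(),
        sex=synth.FEMALE,
        mean_scaffold_length=300_000,
        gene_counts={synth.AUTOSOME: 30, synth.Z_PAR: 16, synth.Z_DR: 40},
        seed=11,
    )


@pytest.fixture
def small_sample(small_config) -> synth.SimulatedSample:
    return synth.simulate_sample(small_config)


def run_preset_replicate(variant: str, seed: int, sex: str | None = None) -> dict:
    """One full in-memory pipeline pass on a packaged preset; returns the
    recovered quantities next to the planted truth."""
    cfg = synth.manakin_preset(variant, seed=seed)
    if sex is not None:
        cfg = dataclasses.replace(cfg, sex=sex)
    t0 = time.perf_counter()
    sample = synth.simulate_sample(cfg)
    windows, peak = zdepth.profile_windows(sample.windows)
    summaries = zclassify.summarize_alignment_rates(
        sample.alignments, sample.scaffolds.lengths(), cfg.reference_z_name)
    zcalls = zclassify.classify_z_scaffolds(summaries)
    sexcall = zclassify.infer_sex(windows, zcalls)
    out = {
        "seed": seed,
        "sex_call": sexcall.call,
        "z_modal_depth": sexcall.z_modal_depth,
        "z_length": int(zcalls.loc[zcalls["call"] == zclassify.Z_CANDIDATE,
                                   "length"].sum()),
        "true_z_length": cfg.karyotype.z_length,
        "true_par_length": cfg.karyotype.class_length(synth.Z_PAR),
        "true_par_genes": cfg.gene_counts.get(synth.Z_PAR, 0),
        "flagged": False,
    }
    if sexcall.call == "FEMALE":
        z_sum = zcalls[zcalls["call"] == zclassify.Z_CANDIDATE]
        placements = pseudoz.anchor_scaffolds(z_sum)
        proj = pseudoz.project_windows(placements, windows)
        segments = zclassify.segment_depth_track(proj)
        by_name = {p.scaffold: p for p in placements}
        gene_rows = [pseudoz.project_interval(by_name[r.chrom], r.start, r.end)
                     + (r.name,)
                     for r in sample.genes.itertuples(index=False)
                     if r.chrom in by_name]
        genes_pseudo = pd.DataFrame(gene_rows, columns=["start", "end", "name"])
        segments = zclassify.count_genes_in_segments(segments, genes_pseudo)
        par = segments[segments["label"] == "PAR"]
        out["par_length"] = int((par["end"] - par["start"]).sum())
        out["par_genes"] = int(par["gene_count"].sum())
        reversal = zclassify.detect_reversal(segments,
                                             cfg.ancestral_par_length)
        out["flagged"] = reversal.flagged
    out["elapsed_s"] = time.perf_counter() - t0
    return out


@pytest.fixture(scope="session")
def typical_female_replicates() -> list[dict]:
    return [run_preset_replicate("typical", seed) for seed in range(20)]


@pytest.fixture(scope="session")
def typical_male_replicates() -> list[dict]:
    return [run_preset_replicate("typical", seed, sex=synth.MALE)
            for seed in range(100, 120)]


@pytest.fixture(scope="session")
def reversal_replicates() -> list[dict]:
    return [run_preset_replicate("reversal", seed) for seed in range(3)]
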