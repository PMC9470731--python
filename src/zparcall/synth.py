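"""Ground-truthed synthetic draft bird genomes for exercising the Z/PAR pipeline.

The generator emulates the situation the pipeline is built for: a ~1 Gb-class
avian genome assembled into scaffolds, sequenced at moderate depth, where the
Z chromosome consists of a differentiated region (DR, single-copy in the
heterogametic female) and a pseudoautosomal region (PAR, two copies in both
sexes), plus optional W-derived sequence. Rather than simulating reads, the
generator emits the first artifacts the pipeline's bespoke computation
consumes: scaffold lengths, per-window mean depths, whole-genome-alignment
records against a reference Z, and planted gene annotations — each with the
ground truth recorded alongside.

Depth noise is gamma-Poisson (negative binomial): the per-window depth sum
S ~ Poisson(lambda * span) with lambda ~ Gamma(shape=k, mean=m), where m is
the expected per-base depth (autosomal mean x copy factor) and k is the
dispersion parameter. Large k recovers the Poisson limit; the default k=100
gives roughly a 10% coefficient of variation on 5 Kb window means at 30x,
a typical magnitude for short-read resequencing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as zio

AUTOSOME = "AUTOSOME"
Z_PAR = "Z_PAR"
Z_DR = "Z_DR"
W = "W"
REGION_CLASSES = (AUTOSOME, Z_PAR, Z_DR, W)

MALE = "MALE"
FEMALE = "FEMALE"

#: Expected copy number relative to autosomes, per region class and sex.
#: Birds are ZW: females carry one Z (DR at half depth) and one W; the PAR
#: recombines and is diploid in both sexes.
DEFAULT_COPY_FACTORS: Mapping[tuple[str, str], float] = {
    (AUTOSOME, MALE): 1.0, (AUTOSOME, FEMALE): 1.0,
    (Z_PAR, MALE): 1.0, (Z_PAR, FEMALE): 1.0,
    (Z_DR, MALE): 1.0, (Z_DR, FEMALE): 0.5,
    (W, MALE): 0.0, (W, FEMALE): 0.5,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Region:
    cls: str
    start: int
    end: int

    def __post_init__(self):
        if self.cls not in REGION_CLASSES:
            raise SimulationError(f"unknown region class {self.cls!r}")
        if not 0 <= self.start < self.end:
            raise SimulationError(f"bad region interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int
    regions: tuple[Region, ...]

    def __post_init__(self):
        if self.length <= 0:
            raise SimulationError(f"{self.name}: non-positive length")
        pos = 0
        for reg in self.regions:
            if reg.start != pos:
                raise SimulationError(
                    f"{self.name}: regions must tile [0, length); gap/overlap at {reg.start}")
            pos = reg.end
        if pos != self.length:
            raise SimulationError(f"{self.name}: regions end at {pos}, length is {self.length}")


@dataclass(frozen=True)
class KaryotypeSpec:
    """Chromosome geometry with per-base region classes (the ground truth)."""

    chromosomes: tuple[ChromosomeSpec, ...]

    def __post_init__(self):
        z_chroms = {c.name for c in self.chromosomes
                    for r in c.regions if r.cls in (Z_PAR, Z_DR)}
        if len(z_chroms) > 1:
            raise SimulationError(f"Z regions on more than one chromosome: {sorted(z_chroms)}")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise SimulationError("duplicate chromosome names")

    @property
    def z_name(self) -> Optional[str]:
        for c in self.chromosomes:
            if any(r.cls in (Z_PAR, Z_DR) for r in c.regions):
                return c.name
        return None

    @property
    def z_length(self) -> int:
        name = self.z_name
        return next(c.length for c in self.chromosomes if c.name == name)

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def class_length(self, cls: str) -> int:
        return sum(r.end - r.start for c in self.chromosomes for r in c.regions if r.cls == cls)

    def region_table(self) -> pd.DataFrame:
        rows = [(c.name, r.start, r.end, r.cls)
                for c in self.chromosomes for r in c.regions]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"])


def uniform_chromosome(name: str, length: int, cls: str = AUTOSOME) -> ChromosomeSpec:
    return ChromosomeSpec(name, length, (Region(cls, 0, length),))


@dataclass(frozen=True)
class DepthModel:
    autosomal_mean_depth: float = 30.0
    dispersion: float = 100.0  # Gamma shape k; Poisson limit as k -> inf
    copy_factor: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COPY_FACTORS))

    def __post_init__(self):
        if self.autosomal_mean_depth <= 0:
            raise SimulationError("autosomal_mean_depth must be > 0")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be > 0")
        for key, val in self.copy_factor.items():
            if not 0.0 <= val <= 1.0:
                raise SimulationError(f"copy factor {key} out of [0, 1]")

    def mean_depth(self, cls: str, sex: str) -> float:
        return self.autosomal_mean_depth * self.copy_factor[(cls, sex)]


@dataclass(frozen=True)
class Scaffold:
    name: str
    length: int
    source_chrom: str
    source_start: int
    source_end: int
    composition: Mapping[str, int]  # class -> bases


@dataclass(frozen=True)
class ScaffoldSet:
    scaffolds: tuple[Scaffold, ...]
    karyotype: KaryotypeSpec

    def __iter__(self):
        return iter(self.scaffolds)

    def __len__(self):
        return len(self.scaffolds)

    def lengths(self) -> pd.Series:
        return pd.Series({s.name: s.length for s in self.scaffolds}, name="length")

    def by_name(self, name: str) -> Scaffold:
        for s in self.scaffolds:
            if s.name == name:
                return s
        raise KeyError(name)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.scaffolds:
            majority = max(sorted(s.composition), key=lambda c: s.composition[c])
            rows.append((s.name, s.length, s.source_chrom, s.source_start,
                         s.source_end, majority,
                         s.source_chrom == self.karyotype.z_name))
        return pd.DataFrame(rows, columns=[
            "scaffold", "length", "source_chrom", "source_start", "source_end",
            "majority_class", "is_z"])


@dataclass(frozen=True)
class SimulationConfig:
    karyotype: KaryotypeSpec
    depth_model: DepthModel
    sex: str = FEMALE
    mean_scaffold_length: int = 2_000_000
    window_size: int = 5_000
    z_aligned_fraction: float = 0.9
    background_aligned_fraction: float = 0.05
    gene_counts: Mapping[str, int] = field(default_factory=dict)
    gene_length: int = 20_000
    reference_z_name: str = "ref_chrZ"
    ancestral_par_length: int = 610_563
    seed: int = 0

    def __post_init__(self):
        if self.sex not in (MALE, FEMALE):
            raise SimulationError(f"sex must be {MALE} or {FEMALE}")
        if self.mean_scaffold_length < 10 * self.window_size:
            raise SimulationError("mean scaffold length must span at least 10 windows")
        for frac in (self.z_aligned_fraction, self.background_aligned_fraction):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("aligned fractions must lie in [0, 1]")
        if self.seed is None:
            raise SimulationError("seed must be explicit")


# --- presets -----------------------------------------------------------------

# Z geometry of the two study configurations. "typical" is the conserved avian
# arrangement: a ~75.5 Mb Z with a ~610 Kb PAR holding 11 genes (574 more on
# the DR, 585 Z genes in total). "reversal" is the anomalous configuration in
# which a ~30 Mb block ordinarily differentiated behaves pseudoautosomally
# (228 genes at diploid female depth), the signature of a DR-to-PAR/autosome
# reversal.
_TYPICAL_Z_LEN = 75_476_763
_TYPICAL_PAR_LEN = 610_563
_TYPICAL_PAR_GENES = 11
_TYPICAL_Z_GENES = 585
_REVERSAL_Z_LEN = 74_940_613
_REVERSAL_PAR_LEN = 29_966_716
_REVERSAL_PAR_GENES = 228
_REVERSAL_Z_GENES = 602

#: Autosomal complement used by both presets: a 200 Mb subset standing in for
#: the macro-chromosome fraction of a ~1.1 Gb genome, plus a small W
#: complement (draft female assemblies recover little W sequence).
_PRESET_AUTOSOMES = (("chr1", 70_000_000), ("chr2", 60_000_000),
                     ("chr3", 40_000_000), ("chr4", 30_000_000))
_PRESET_W_LEN = 7_000_000
_PRESET_AUTOSOME_GENES = 2_000


def manakin_preset(variant: str = "typical", seed: int = 0) -> SimulationConfig:
    """Packaged female simulation scenarios mirroring the two observed Z layouts.

    ``typical``: conserved ~610 Kb PAR at the Z tip. ``reversal``: ~30 Mb
    PAR-like block (ancestrally differentiated) at the Z tip.
    """
    if variant == "typical":
        z_len, par_len = _TYPICAL_Z_LEN, _TYPICAL_PAR_LEN
        par_genes, dr_genes = _TYPICAL_PAR_GENES, _TYPICAL_Z_GENES - _TYPICAL_PAR_GENES
    elif variant == "reversal":
        z_len, par_len = _REVERSAL_Z_LEN, _REVERSAL_PAR_LEN
        par_genes, dr_genes = _REVERSAL_PAR_GENES, _REVERSAL_Z_GENES - _REVERSAL_PAR_GENES
    else:
        raise SimulationError(f"unknown preset variant {variant!r}")
    chroms = [uniform_chromosome(name, length) for name, length in _PRESET_AUTOSOMES]
    chroms.append(ChromosomeSpec("chrZ", z_len, (
        Region(Z_PAR, 0, par_len), Region(Z_DR, par_len, z_len))))
    chroms.append(uniform_chromosome("chrW", _PRESET_W_LEN, W))
    return SimulationConfig(
        karyotype=KaryotypeSpec(tuple(chroms)),
        depth_model=DepthModel(),
        sex=FEMALE,
        gene_counts={AUTOSOME: _PRESET_AUTOSOME_GENES, Z_PAR: par_genes,
                     Z_DR: dr_genes, W: 0},
        ancestral_par_length=_TYPICAL_PAR_LEN,
        seed=seed,
    )


# --- fragmentation -----------------------------------------------------------

def fragment_scaffolds(karyotype: KaryotypeSpec, mean_length: int,
                       seed: int) -> ScaffoldSet:
    """Cut chromosomes into scaffolds at Poisson-process breakpoints.

    Inter-breakpoint distances are exponential with the given mean, so total
    length is conserved exactly and a chromosome shorter than the mean
    degenerates to a single scaffold.
    """
    if mean_length <= 0:
        raise SimulationError("mean_length must be > 0")
    rng = np.random.default_rng(seed)
    scaffolds: list[Scaffold] = []
    idx = 0
    for chrom in karyotype.chromosomes:
        cuts = []
        pos = 0.0
        while True:
            pos += rng.exponential(mean_length)
            if pos >= chrom.length:
                break
            cuts.append(int(round(pos)))
        edges = sorted({0, chrom.length, *[c for c in cuts if 0 < c < chrom.length]})
        for start, end in zip(edges[:-1], edges[1:]):
            comp = _composition(chrom, start, end)
            scaffolds.append(Scaffold(
                name=f"scaffold_{idx:05d}", length=end - start,
                source_chrom=chrom.name, source_start=start, source_end=end,
                composition=comp))
            idx += 1
    return ScaffoldSet(tuple(scaffolds), karyotype)


def _composition(chrom: ChromosomeSpec, start: int, end: int) -> dict[str, int]:
    comp: dict[str, int] = {}
    for reg in chrom.regions:
        ov = min(end, reg.end) - max(start, reg.start)
        if ov > 0:
            comp[reg.cls] = comp.get(reg.cls, 0) + ov
    return comp


def _window_classes(scaffold: Scaffold, chrom: ChromosomeSpec,
                    starts: np.ndarray, ends: np.ndarray) -> list[str]:
    """Majority region class of each window (ties broken by class name)."""
    out = []
    for ws, we in zip(starts, ends):
        comp = _composition(chrom, scaffold.source_start + int(ws),
                            scaffold.source_start + int(we))
        out.append(max(sorted(comp), key=lambda c: comp[c]))
    return out


# --- window depths -----------------------------------------------------------

def simulate_window_depths(scaffolds: ScaffoldSet, model: DepthModel, sex: str,
                           window: int, seed: int) -> pd.DataFrame:
    """Draw per-window mean depths under the gamma-Poisson model.

    Returns a window table (scaffold, start, end, mean_depth, partial) with
    the ground-truth region class of each window in ``true_class``. The
    window's expected depth is set by the majority class of its footprint.
    """
    if window <= 0:
        raise SimulationError("window must be > 0")
    rng = np.random.default_rng(seed)
    frames = []
    for scaf in scaffolds:
        chrom = scaffolds.karyotype.chromosome(scaf.source_chrom)
        starts = np.arange(0, scaf.length, window, dtype=np.int64)
        ends = np.minimum(starts + window, scaf.length)
        classes = _window_classes(scaf, chrom, starts, ends)
        frames.append(pd.DataFrame({
            "scaffold": scaf.name, "start": starts, "end": ends,
            "true_class": classes}))
    table = pd.concat(frames, ignore_index=True)
    spans = (table["end"] - table["start"]).to_numpy()
    means = np.array([model.mean_depth(cls, sex) for cls in table["true_class"]])
    k = model.dispersion
    lam = np.where(means > 0, rng.gamma(k, np.maximum(means, 1e-300) / k), 0.0)
    counts = rng.poisson(lam * spans)
    table["mean_depth"] = counts / spans
    table["partial"] = spans < window
    return table[["scaffold", "start", "end", "mean_depth", "partial", "true_class"]]


# --- alignments --------------------------------------------------------------

def simulate_alignments(scaffolds: ScaffoldSet, config: SimulationConfig,
                        seed: Optional[int] = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit PAF records tying Z-derived scaffolds to the reference Z.

    Z-derived scaffolds receive alignment blocks at their true source
    coordinates covering ~``z_aligned_fraction`` of their length; other
    scaffolds receive spurious blocks covering at most
    ``background_aligned_fraction``. Each scaffold's orientation relative to
    the reference is drawn at random and returned as truth alongside the PAF.
    """
    karyotype = scaffolds.karyotype
    z_name = karyotype.z_name
    if z_name is None:
        raise SimulationError("karyotype has no Z chromosome")
    z_len = karyotype.z_length
    rng = np.random.default_rng(config.seed + 7_919 if seed is None else seed)
    paf_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    mean_f = config.z_aligned_fraction
    conc = 200.0  # Beta concentration: small spread around the mean fraction
    for scaf in scaffolds:
        L = scaf.length
        strand = "+" if rng.random() < 0.5 else "-"
        is_z = scaf.source_chrom == z_name
        truth_rows.append((scaf.name, strand, is_z))
        if is_z:
            f = rng.beta(mean_f * conc, (1 - mean_f) * conc)
            aligned = int(round(f * L))
            nblocks = 1 + rng.poisson(L / 1e6)
            block_lens = _split_total(rng, aligned, nblocks)
            gap_lens = _split_total(rng, L - aligned, len(block_lens) + 1,
                                    keep_zeros=True)
            q = gap_lens[0]
            for i, blen in enumerate(block_lens):
                qs, qe = q, q + blen
                q = qe + gap_lens[i + 1]
                if strand == "+":
                    ts, te = scaf.source_start + qs, scaf.source_start + qe
                else:
                    ts, te = scaf.source_start + L - qe, scaf.source_start + L - qs
                paf_rows.append((scaf.name, L, qs, qe, strand,
                                 config.reference_z_name, z_len, ts, te,
                                 int(round(0.95 * blen)), blen, 60))
        else:
            nblocks = rng.poisson(0.7)
            if nblocks == 0:
                continue
            cov = rng.uniform(0.0, config.background_aligned_fraction)
            block_lens = _split_total(rng, int(cov * L), nblocks)
            for blen in block_lens:
                if blen < 50:
                    continue
                qs = int(rng.integers(0, L - blen + 1))
                ts = int(rng.integers(0, z_len - blen + 1))
                bstrand = "+" if rng.random() < 0.5 else "-"
                paf_rows.append((scaf.name, L, qs, qs + blen, bstrand,
                                 config.reference_z_name, z_len, ts, ts + blen,
                                 int(round(0.7 * blen)), blen, 10))
    paf = pd.DataFrame(paf_rows, columns=zio.PAF_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["scaffold", "true_strand", "is_z"])
    return paf, truth


def _split_total(rng: np.random.Generator, total: int, parts: int,
                 keep_zeros: bool = False) -> list[int]:
    """Split ``total`` bases into ``parts`` non-negative pieces. With
    ``keep_zeros=False`` zero-length pieces are dropped (a positive total
    always keeps at least one piece)."""
    if parts < 1:
        return []
    if parts == 1 or total <= 0:
        tail = [0] * (parts - 1) if keep_zeros else []
        return ([total] if total > 0 or keep_zeros else []) + tail
    cuts = np.sort(rng.integers(0, total + 1, size=parts - 1))
    lens = np.diff(np.concatenate([[0], cuts, [total]]))
    if keep_zeros:
        return [int(v) for v in lens]
    out = [int(v) for v in lens if v > 0]
    return out or [total]


# --- gene planting -----------------------------------------------------------

def plant_genes(karyotype: KaryotypeSpec, counts: Mapping[str, int], seed: int,
                gene_length: int = 20_000) -> pd.DataFrame:
    """Place non-overlapping gene intervals uniformly within each region class.

    Counts are exact per class. Returns a BED-like frame in chromosome
    coordinates with the class recorded in ``cls`` (truth) and sequential
    names per class.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls in REGION_CLASSES:
        n_total = int(counts.get(cls, 0))
        if n_total < 0:
            raise SimulationError(f"negative gene count for {cls}")
        if n_total == 0:
            continue
        regions = [(c.name, r.start, r.end) for c in karyotype.chromosomes
                   for r in c.regions if r.cls == cls]
        if not regions:
            raise SimulationError(f"no {cls} region to hold {n_total} genes")
        lens = np.array([e - s for _, s, e in regions], dtype=float)
        alloc = _largest_remainder(lens / lens.sum() * n_total)
        gidx = 0
        for (chrom, rs, re_), n in zip(regions, alloc):
            if n == 0:
                continue
            free = (re_ - rs) - n * gene_length
            if free < 0:
                raise SimulationError(
                    f"{cls} region on {chrom} too small for {n} genes of {gene_length} bp")
            offsets = np.sort(rng.uniform(0, free + 1, size=n)).astype(np.int64)
            starts = rs + offsets + np.arange(n, dtype=np.int64) * gene_length
            for s in starts:
                rows.append((chrom, int(s), int(s) + gene_length,
                             f"g{cls}_{gidx:04d}", cls))
                gidx += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "cls"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def _largest_remainder(target: np.ndarray) -> np.ndarray:
    floor = np.floor(target).astype(int)
    short = int(round(target.sum())) - floor.sum()
    order = np.argsort(-(target - floor), kind="stable")
    floor[order[:short]] += 1
    return floor


def project_genes_to_scaffolds(genes: pd.DataFrame,
                               scaffolds: ScaffoldSet) -> pd.DataFrame:
    """Lift chromosome-coordinate genes onto scaffold coordinates.

    A gene straddling a scaffold breakpoint is assigned to the scaffold
    holding the majority of its span and clipped to that scaffold.
    """
    by_chrom: dict[str, list[Scaffold]] = {}
    for s in scaffolds:
        by_chrom.setdefault(s.source_chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.source_start)
    rows = []
    for rec in genes.itertuples(index=False):
        best, best_ov = None, 0
        for s in by_chrom.get(rec.chrom, ()):
            ov = min(rec.end, s.source_end) - max(rec.start, s.source_start)
            if ov > best_ov:
                best, best_ov = s, ov
        if best is None:
            continue
        start = max(rec.start, best.source_start) - best.source_start
        end = min(rec.end, best.source_end) - best.source_start
        rows.append((best.name, start, end, rec.name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# --- whole-scenario driver ---------------------------------------------------

@dataclass(frozen=True)
class SimulatedSample:
    config: SimulationConfig
    scaffolds: ScaffoldSet
    windows: pd.DataFrame        # raw window depths with truth classes
    alignments: pd.DataFrame     # PAF records
    alignment_truth: pd.DataFrame
    genes_chrom: pd.DataFrame    # chromosome coordinates, with truth class
    genes: pd.DataFrame          # scaffold coordinates (assembly-facing)


def simulate_sample(config: SimulationConfig) -> SimulatedSample:
    """Run the full generator with seeds derived from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    scaffolds = fragment_scaffolds(config.karyotype, config.mean_scaffold_length,
                                   int(sub[0]))
    windows = simulate_window_depths(scaffolds, config.depth_model, config.sex,
                                     config.window_size, int(sub[1]))
    paf, truth = simulate_alignments(scaffolds, config, int(sub[2]))
    genes_chrom = plant_genes(config.karyotype, config.gene_counts, int(sub[3]),
                              config.gene_length)
    genes = project_genes_to_scaffolds(genes_chrom, scaffolds)
    return SimulatedSample(config, scaffolds, windows, paf, truth,
                           genes_chrom, genes)


def write_sample(sample: SimulatedSample, out_dir) -> dict[str, str]:
    """Write all assembly-facing and truth files; returns name -> path."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lengths": out / "scaffolds.fai",
        "windows": out / "windows.tsv",
        "alignments": out / "alignments.paf",
        "genes": out / "genes.bed",
        "truth_scaffolds": out / "truth_scaffolds.tsv",
        "truth_windows": out / "truth_windows.bed",
        "truth_genes": out / "truth_genes.bed",
    }
    zio.write_fai(sample.scaffolds.lengths(), paths["lengths"])
    zio.write_window_table(sample.windows, paths["windows"])
    zio.write_paf(sample.alignments, paths["alignments"])
    zio.write_bed(sample.genes.rename(columns={}), paths["genes"])
    sample.scaffolds.truth_table().to_csv(paths["truth_scaffolds"], sep="\t", index=False)
    truth_windows = sample.windows.rename(columns={"scaffold": "chrom",
                                                   "true_class": "name"})
    zio.write_bed(truth_windows[["chrom", "start", "end", "name"]], paths["truth_windows"])
    zio.write_bed(sample.genes_chrom.rename(columns={"cls": "score"}),
                  paths["truth_genes"])
    return {k: str(v) for k, v in paths.items()}
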