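"""Synthetic-data generator for every input the pipeline consumes.

The generator emulates a 2x2 gnotobiotic design — genotype (WT vs TF
mutant) crossed with colonization (germ-free GF vs conventionalized CV) —
with planted per-gene effect classes:

* ``suppressed_activated``  higher in GF than CV (microbiota-suppressed)
  and higher in WT than Mut (TF-activated); the class the analysis is
  designed to surface;
* ``suppressed_repressed``, ``induced_activated``, ``induced_repressed``
  the remaining fold-change quadrants;
* ``colonization_only`` / ``genotype_only`` single-axis effects with a
  random sign;
* ``null`` no planted effect.

Counts are negative binomial with additive log2 effects and no
genotype x colonization interaction by default.  Each planted-effect gene
receives one TF binding peak within 10 kb of its TSS whose
condition-specificity follows the gene's microbiota direction
(suppressed genes lose their peak upon colonization with probability
``peak_gf_bias``, induced genes gain one); null genes receive background
peaks at a low rate, placed uniformly over the genome.  Coverage tracks
carry a triangular signal bump at every peak summit over a flat
background.  Ortholog tables chain the simulated genes through a mouse-like
to a human-like namespace with dropout and paralog noise, and the disease
list draws its log2 fold changes from the planted genotype effect through
a configurable structural slope, which is what the Deming stage recovers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffcount import CountMatrix
from .errors import CapacityError
from .formats import (
    GeneRecord,
    GenomicRegion,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_counts,
    write_design,
    write_gene_annotation,
    write_ortholog_table,
)
from .orthologs import DiseaseGeneSet
from .regions import PeakSet

GENE_CLASSES = (
    "null",
    "suppressed_activated",
    "suppressed_repressed",
    "induced_activated",
    "induced_repressed",
    "colonization_only",
    "genotype_only",
)

DESIGN_CELLS = (("WT", "CV"), ("WT", "GF"), ("Mut", "CV"), ("Mut", "GF"))


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 40_000_000, "chr2": 40_000_000, "chr3": 40_000_000}


def _default_n_reps() -> dict[str, int]:
    # replicate structure of the 2x2 transcriptome design: 3 WT, 2 Mut
    return {"WTCV": 3, "WTGF": 3, "MutCV": 2, "MutGF": 2}


def _default_class_fractions() -> dict[str, float]:
    # The TF is an activator on both sides: 90% of microbiota-suppressed
    # and 90% of microbiota-induced coregulated genes are TF-activated.
    # The symmetric split leaves the planted microbiota and genotype
    # effects uncorrelated across genes, so the genotype axis carries the
    # disease slope while the colonization axis is a genuine null for it.
    return {
        "null": 0.70,
        "suppressed_activated": 0.09,
        "suppressed_repressed": 0.01,
        "induced_activated": 0.09,
        "induced_repressed": 0.01,
        "colonization_only": 0.05,
        "genotype_only": 0.05,
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_genes: int = 2000
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_reps: dict[str, int] = field(default_factory=_default_n_reps)
    class_fractions: dict[str, float] = field(
        default_factory=_default_class_fractions
    )
    effect_size: float = 2.0  # |log2FC| of planted effects
    interaction: float = 0.0  # extra log2 effect in the WT-GF cell
    dispersion: float = 0.1  # NB alpha
    base_mean_log_range: tuple[float, float] = (3.0, 10.0)  # log2 units
    library_factor_range: tuple[float, float] = (0.7, 1.4)
    tss_min_spacing: int = 2000
    # peaks / coverage
    peak_gf_bias: float = 0.8
    background_peak_rate: float = 0.05
    peak_width: tuple[int, int] = (200, 400)
    peak_max_offset: int = 8000  # summit-to-TSS, < 10 kb assignment cutoff
    bump_height: float = 40.0
    bump_halfwidth: int = 600
    background_coverage: float = 1.0
    track_resolution: int = 25
    track_halfwidth: int = 1600
    read_length: int = 100
    # region counts
    region_reps: int = 3
    region_mean_present: float = 80.0
    region_mean_absent: float = 4.0
    # orthology / disease
    ortholog_dropout: float = 0.1
    paralog_rate: float = 0.05
    disease_label: str = "iCD"
    disease_true_slope: float = 0.8
    disease_noise_sd_x: float = 0.3
    disease_noise_sd_y: float = 0.3
    disease_min_abs_fc: float = 0.25
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        for name in (
            "peak_gf_bias",
            "background_peak_rate",
            "ortholog_dropout",
            "paralog_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for cell, r in self.n_reps.items():
            if r < 2:
                raise ValueError(f"n_reps[{cell!r}] = {r}; >= 2 required")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.disease_noise_sd_x <= 0 or self.disease_noise_sd_y <= 0:
            raise ValueError("disease noise SDs must be > 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted values recorded for parameter-recovery tests."""

    gene_ids: list[str]
    class_label: np.ndarray  # str per gene
    microbiota_effect: np.ndarray  # true log2(GF/CV) within WT
    genotype_effect: np.ndarray  # true log2(WT/Mut) within CV
    baseline_log2: np.ndarray
    library_factors: pd.Series | None = None
    peak_table: pd.DataFrame | None = None  # gene_id/name, specificity
    ortholog_truth: pd.DataFrame | None = None  # human, mouse, zebrafish
    disease_detail: pd.DataFrame | None = None  # x_star, x_obs, y, kept
    disease_true_slope: float | None = None

    def classes(self) -> pd.Series:
        return pd.Series(self.class_label, index=self.gene_ids, name="class")

    def as_json_dict(self) -> dict:
        out = {
            "gene_ids": self.gene_ids,
            "class_label": list(map(str, self.class_label)),
            "microbiota_effect": self.microbiota_effect.tolist(),
            "genotype_effect": self.genotype_effect.tolist(),
            "baseline_log2": self.baseline_log2.tolist(),
            "disease_true_slope": self.disease_true_slope,
        }
        if self.peak_table is not None:
            out["peak_table"] = self.peak_table.to_dict(orient="list")
        if self.ortholog_truth is not None:
            out["ortholog_truth"] = self.ortholog_truth.to_dict(orient="list")
        return out


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GeneRecord]:
    """Place n_genes TSSs uniformly with a minimum spacing per chromosome."""
    sizes = config.chrom_sizes
    if not sizes:
        raise ValueError("chrom_sizes must be non-empty")
    total = sum(sizes.values())
    chroms = sorted(sizes)
    alloc = {c: int(config.n_genes * sizes[c] / total) for c in chroms}
    leftover = config.n_genes - sum(alloc.values())
    for c in chroms[:leftover]:
        alloc[c] += 1
    spacing = config.tss_min_spacing
    width = len(str(config.n_genes))
    genes: list[GeneRecord] = []
    counter = 0
    for chrom in chroms:
        k = alloc[chrom]
        if k == 0:
            continue
        slack = sizes[chrom] - (k - 1) * spacing
        if slack <= 0:
            raise CapacityError(
                f"{chrom} ({sizes[chrom]} bp) cannot hold {k} genes at "
                f"{spacing} bp spacing"
            )
        raw = np.sort(rng.integers(0, slack, size=k))
        tss = raw + spacing * np.arange(k)
        strands = rng.choice(["+", "-"], size=k)
        for t, s in zip(tss, strands):
            genes.append(GeneRecord(f"g{counter:0{width}d}", chrom, str(s), int(t)))
            counter += 1
    return genes


# ---------------------------------------------------------------------------
# counts


def _planted_effects(
    config: SimulationConfig, labels: np.ndarray, rng: np.random.Generator
):
    e = config.effect_size
    n = labels.size
    mu = np.zeros(n)  # log2(GF/CV) within WT
    gamma = np.zeros(n)  # log2(WT/Mut) within CV
    signs = {
        "suppressed_activated": (+1, +1),
        "suppressed_repressed": (+1, -1),
        "induced_activated": (-1, +1),
        "induced_repressed": (-1, -1),
    }
    for label, (sm, sg) in signs.items():
        mask = labels == label
        mu[mask] = sm * e
        gamma[mask] = sg * e
    for label, target in (("colonization_only", mu), ("genotype_only", gamma)):
        mask = labels == label
        target[mask] = rng.choice([-e, e], size=int(mask.sum()))
    return mu, gamma


def simulate_counts(
    annotation: list[GeneRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[CountMatrix, GroundTruth]:
    """NB counts for the 2x2 design with planted additive log2 effects."""
    if not annotation:
        raise ValueError("annotation must be non-empty")
    gene_ids = [g.gene_id for g in annotation]
    n = len(gene_ids)
    fractions = [config.class_fractions.get(c, 0.0) for c in GENE_CLASSES]
    labels = rng.choice(GENE_CLASSES, size=n, p=fractions)
    mu, gamma = _planted_effects(config, labels, rng)
    lo, hi = config.base_mean_log_range
    baseline = rng.uniform(lo, hi, size=n)

    samples, genos, cols, reps = [], [], [], []
    for geno, col in DESIGN_CELLS:
        cell = f"{geno}{col}"
        for i in range(1, config.n_reps[cell] + 1):
            samples.append(f"{cell}_{i}")
            genos.append(geno)
            cols.append(col)
            reps.append(i)
    design = pd.DataFrame(
        {"genotype": genos, "colonization": cols, "replicate": reps},
        index=pd.Index(samples, name="sample"),
    )
    f_lo, f_hi = config.library_factor_range
    lib = 2.0 ** rng.uniform(np.log2(f_lo), np.log2(f_hi), size=len(samples))

    is_gf = np.array([c == "GF" for c in cols], dtype=float)
    is_wt = np.array([g == "WT" for g in genos], dtype=float)
    log2_mean = (
        baseline[:, None]
        + mu[:, None] * is_gf[None, :]
        + gamma[:, None] * is_wt[None, :]
        + config.interaction * (is_gf * is_wt)[None, :]
    )
    mean = (2.0**log2_mean) * lib[None, :]
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.int64)

    cm = CountMatrix(gene_ids, counts, design)
    truth = GroundTruth(
        gene_ids=gene_ids,
        class_label=labels.astype(str),
        microbiota_effect=mu,
        genotype_effect=gamma,
        baseline_log2=baseline,
        library_factors=pd.Series(lib, index=samples),
        disease_true_slope=config.disease_true_slope,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# peaks and coverage


def _make_track(
    peaks: list[GenomicRegion],
    chrom_sizes: dict[str, int],
    config: SimulationConfig,
    heights: np.ndarray,
) -> SignalTrack:
    """Flat background plus a triangular bump at each peak summit."""
    step = config.track_resolution
    W = config.track_halfwidth
    hw = float(config.bump_halfwidth)
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for peak, h in zip(peaks, heights):
        by_chrom.setdefault(peak.chrom, []).append((peak.reference_point, float(h)))
    intervals: list[tuple[str, int, int, float]] = []
    for chrom, summits in sorted(by_chrom.items()):
        summits.sort()
        size = chrom_sizes.get(chrom, max(s for s, _ in summits) + W)
        # merge overlapping windows around nearby summits
        merged: list[list] = []
        for s, h in summits:
            a, b = max(0, s - W), min(size, s + W)
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
                merged[-1][2].append((s, h))
            else:
                merged.append([a, b, [(s, h)]])
        for a, b, members in merged:
            grid = np.arange(a, b, step, dtype=np.int64)
            ends = np.minimum(grid + step, b)
            mids = (grid + ends) / 2.0
            vals = np.full(grid.shape, config.background_coverage)
            for s, h in members:
                vals += h * np.maximum(0.0, 1.0 - np.abs(mids - s) / hw)
            for g, e, v in zip(grid, ends, vals):
                intervals.append((chrom, int(g), int(e), float(v)))
    mass = sum(v * (e - s) for _, s, e, v in intervals)
    library_size = max(1.0, mass / config.read_length)
    return SignalTrack(intervals, library_size)


def simulate_peaks(
    annotation: list[GeneRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[PeakSet, PeakSet, SignalTrack, SignalTrack]:
    """Condition-specific peak sets and coverage tracks.

    Every planted-effect gene receives one peak whose summit lies within
    10 kb of its TSS.  Condition-specificity follows the gene's microbiota
    direction with probability ``peak_gf_bias`` (suppressed -> GF-only,
    induced -> CV-only); microbiota-neutral planted genes and background
    peaks are shared.  The resulting peak truth table is recorded on
    ``truth.peak_table``.
    """
    genes = {g.gene_id: g for g in annotation}
    classes = truth.classes()
    mu = pd.Series(truth.microbiota_effect, index=truth.gene_ids)
    planted = [gid for gid, c in classes.items() if c != "null"]

    rows = []
    gf_regions: list[GenomicRegion] = []
    cv_regions: list[GenomicRegion] = []
    heights_gf: list[float] = []
    heights_cv: list[float] = []
    wlo, whi = config.peak_width
    for gid in planted:
        g = genes[gid]
        chrom_size = config.chrom_sizes[g.chrom]
        width = int(rng.integers(wlo, whi + 1))
        offset = int(rng.integers(-config.peak_max_offset, config.peak_max_offset + 1))
        center = int(np.clip(g.tss + offset, width, chrom_size - width))
        region = GenomicRegion(
            g.chrom, center - width // 2, center - width // 2 + width,
            name=f"peak_{gid}", summit_offset=width // 2,
        )
        direction = np.sign(mu[gid])
        if direction > 0:
            specificity = "GF_only" if rng.random() < config.peak_gf_bias else "shared"
        elif direction < 0:
            specificity = "CV_only" if rng.random() < config.peak_gf_bias else "shared"
        else:
            specificity = "shared"
        h = config.bump_height * rng.uniform(0.8, 1.2)
        if specificity in ("GF_only", "shared"):
            gf_regions.append(region)
            heights_gf.append(h)
        if specificity in ("CV_only", "shared"):
            cv_regions.append(region)
            heights_cv.append(h)
        rows.append((region.name, gid, specificity))

    n_null = int((classes == "null").sum())
    n_bg = int(rng.binomial(n_null, config.background_peak_rate))
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for i in range(n_bg):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        width = int(rng.integers(wlo, whi + 1))
        start = int(rng.integers(0, config.chrom_sizes[chrom] - width))
        region = GenomicRegion(
            chrom, start, start + width, name=f"bgpeak_{i:04d}",
            summit_offset=width // 2,
        )
        h = config.bump_height * rng.uniform(0.8, 1.2)
        gf_regions.append(region)
        cv_regions.append(region)
        heights_gf.append(h)
        heights_cv.append(h)
        rows.append((region.name, None, "background"))

    truth.peak_table = pd.DataFrame(
        rows, columns=["peak_name", "gene_id", "specificity"]
    )
    gf = PeakSet("GF", gf_regions)
    cv = PeakSet("CV", cv_regions)
    track_gf = _make_track(gf_regions, config.chrom_sizes, config, np.array(heights_gf))
    track_cv = _make_track(cv_regions, config.chrom_sizes, config, np.array(heights_cv))
    return gf, cv, track_gf, track_cv


def simulate_region_counts(
    gf: PeakSet,
    cv: PeakSet,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[CountMatrix, dict[str, GenomicRegion]]:
    """NB read counts over the union of peaks, per condition replicate.

    Regions present in a condition's peak set have mean
    ``region_mean_present`` there and ``region_mean_absent`` where absent,
    which is what makes condition-specific peaks differential at q < 0.01.
    """
    union: dict[str, GenomicRegion] = {}
    in_gf: set[str] = set()
    in_cv: set[str] = set()
    for r in gf.regions:
        union[r.name] = r
        in_gf.add(r.name)
    for r in cv.regions:
        union[r.name] = r
        in_cv.add(r.name)
    names = sorted(union)
    mean_gf = np.array(
        [config.region_mean_present if n in in_gf else config.region_mean_absent
         for n in names]
    )
    mean_cv = np.array(
        [config.region_mean_present if n in in_cv else config.region_mean_absent
         for n in names]
    )
    reps = config.region_reps
    samples = [f"regGF_{i}" for i in range(1, reps + 1)] + [
        f"regCV_{i}" for i in range(1, reps + 1)
    ]
    design = pd.DataFrame(
        {
            "genotype": ["WT"] * 2 * reps,
            "colonization": ["GF"] * reps + ["CV"] * reps,
            "replicate": list(range(1, reps + 1)) * 2,
        },
        index=pd.Index(samples, name="sample"),
    )
    lib = 2.0 ** rng.uniform(-0.15, 0.15, size=2 * reps)
    mean = np.concatenate(
        [np.tile(mean_gf[:, None], reps), np.tile(mean_cv[:, None], reps)], axis=1
    ) * lib[None, :]
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.int64)
    return CountMatrix(names, counts, design), union


# ---------------------------------------------------------------------------
# orthologs and disease lists


def simulate_ortholog_tables(
    annotation: list[GeneRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise ortholog tables (human<->mouse, mouse<->zebrafish).

    Each simulated gene keeps its ortholog with probability
    1 - ortholog_dropout per link; with probability paralog_rate a
    conflicting many-to-one pair is injected, which the one-to-one filter
    must remove.  Returns (human-mouse pairs, mouse-zebrafish pairs,
    truth table of complete unconflicted chains).
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    hm_rows: list[tuple[str, str]] = []
    mz_rows: list[tuple[str, str]] = []
    truth_rows = []
    for g in annotation:
        z = g.gene_id
        if rng.random() < config.ortholog_dropout:
            continue
        m = f"m_{z}"
        mz_rows.append((m, z))
        mz_conflict = rng.random() < config.paralog_rate
        if mz_conflict:
            mz_rows.append((f"m_{z}_par", z))
        if rng.random() < config.ortholog_dropout:
            continue
        h = f"h_{z}"
        hm_rows.append((h, m))
        hm_conflict = rng.random() < config.paralog_rate
        if hm_conflict:
            hm_rows.append((f"h_{z}_par", m))
        if not (mz_conflict or hm_conflict):
            truth_rows.append((h, m, z))
    hm = pd.DataFrame(hm_rows, columns=["gene_a", "gene_b"])
    mz = pd.DataFrame(mz_rows, columns=["gene_a", "gene_b"])
    truth = pd.DataFrame(truth_rows, columns=["human", "mouse", "zebrafish"])
    return hm, mz, truth


def simulate_disease_lists(
    truth: GroundTruth,
    ortholog_truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> DiseaseGeneSet:
    """Disease log2 fold changes tied to the planted genotype effect.

    For each fully chained gene the latent disease-relevant effect is the
    true log2FC of the MutCV/WTCV comparison (x* = -genotype_effect); the
    disease value is y = slope * x* + eps_y, and a noisy observed x is
    recorded alongside for standalone regression checks.  Genes pass into
    the published-style list when |y| >= disease_min_abs_fc; the direction
    label is the sign of y.  Detail (x_star, x_obs, y, kept) is stored on
    ``truth.disease_detail``.
    """
    gamma = pd.Series(truth.genotype_effect, index=truth.gene_ids)
    chained = ortholog_truth[ortholog_truth["zebrafish"].isin(gamma.index)]
    x_star = -gamma.loc[chained["zebrafish"]].to_numpy()
    y = (
        config.disease_true_slope * x_star
        + rng.normal(0.0, config.disease_noise_sd_y, size=x_star.size)
    )
    x_obs = x_star + rng.normal(0.0, config.disease_noise_sd_x, size=x_star.size)
    kept = np.abs(y) >= config.disease_min_abs_fc
    detail = pd.DataFrame(
        {
            "human": chained["human"].to_numpy(),
            "zebrafish": chained["zebrafish"].to_numpy(),
            "x_star": x_star,
            "x_obs": x_obs,
            "y": y,
            "kept": kept,
        }
    )
    truth.disease_detail = detail
    table = pd.DataFrame(
        {
            "gene": detail.loc[kept, "human"].to_numpy(),
            "direction": np.where(detail.loc[kept, "y"] >= 0, "up", "down"),
            "log2fc": detail.loc[kept, "y"].to_numpy(),
        }
    )
    return DiseaseGeneSet(config.disease_label, table)


# ---------------------------------------------------------------------------
# one-call simulation and dataset writing


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: list[GeneRecord]
    counts: CountMatrix
    truth: GroundTruth
    peaks_gf: PeakSet
    peaks_cv: PeakSet
    track_gf: SignalTrack
    track_cv: SignalTrack
    region_counts: CountMatrix
    union_regions: dict[str, GenomicRegion]
    orthologs_hm: pd.DataFrame
    orthologs_mz: pd.DataFrame
    disease: DiseaseGeneSet


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator off one seed, with per-stage substreams."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]
    annotation = simulate_annotation(config, rngs[0])
    counts, truth = simulate_counts(annotation, config, rngs[1])
    gf, cv, track_gf, track_cv = simulate_peaks(annotation, truth, config, rngs[2])
    region_counts, union = simulate_region_counts(gf, cv, config, rngs[3])
    hm, mz, ortho_truth = simulate_ortholog_tables(annotation, config, rngs[4])
    truth.ortholog_truth = ortho_truth
    disease = simulate_disease_lists(truth, ortho_truth, config, rngs[4])
    return SimulatedDataset(
        config, annotation, counts, truth, gf, cv, track_gf, track_cv,
        region_counts, union, hm, mz, disease,
    )


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> Path:
    """Write a self-contained dataset directory plus ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_annotation(data.annotation, outdir / "annotation.tsv")
    write_counts(data.counts, outdir / "counts.tsv")
    write_design(data.counts.design, outdir / "design.tsv")
    write_bed(data.peaks_gf.regions, outdir / "peaks_GF.bed")
    write_bed(data.peaks_cv.regions, outdir / "peaks_CV.bed")
    write_bedgraph(data.track_gf, outdir / "coverage_GF.bedgraph")
    write_bedgraph(data.track_cv, outdir / "coverage_CV.bedgraph")
    write_counts(data.region_counts, outdir / "region_counts.tsv")
    write_design(data.region_counts.design, outdir / "region_design.tsv")
    write_ortholog_table(data.orthologs_hm, outdir / "orthologs_human_mouse.tsv")
    write_ortholog_table(data.orthologs_mz, outdir / "orthologs_mouse_zebrafish.tsv")
    data.disease.table.to_csv(outdir / "disease.tsv", sep="\t", index=False)
    manifest = {
        "library_size_GF": data.track_gf.library_size,
        "library_size_CV": data.track_cv.library_size,
        "disease_label": data.disease.disease_label,
        "seed": data.config.seed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(data.truth.as_json_dict(), fh, sort_keys=True)
    return outdir
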