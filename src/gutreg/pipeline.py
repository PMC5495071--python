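"""End-to-end orchestration: simulate (or load) inputs, run every analysis
stage in order, and emit a machine-readable report.

Stage order: differential expression (four contrasts) -> four-way membership
-> quadrant classification -> region differential -> peak-to-gene assignment
-> enhancer/expression KS concordance -> peak-set comparison -> signal
profiles -> ortholog filtering/chaining -> disease enrichment and
association proportions -> Deming concordance grid.

A run is fully determined by (config, seed): one seed feeds per-stage
substreams, and the report JSON is byte-identical across repeat runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import (
    classify_four_way,
    coregulation_summary,
    ks_region_expression,
    quadrant_labels,
)
from .deming import build_pairs, concordance_grid
from .diffcount import (
    CountMatrix,
    ExpressionComparison,
    differential_table,
    write_differential_table,
)
from .errors import StageError
from .formats import (
    read_bed,
    read_bedgraph,
    read_counts,
    read_design,
    read_disease_table,
    read_gene_annotation,
    read_ortholog_table,
)
from .orthologs import (
    DiseaseGeneSet,
    association_proportions,
    chain_orthologs,
    enrichment_table,
    one_to_one_filter,
)
from .regions import (
    PeakSet,
    assign_peaks_to_genes,
    compare_peak_sets,
    flanking_signal_matrix,
    mean_profile,
    write_assignment,
    write_profile_matrix,
)
from .simulate import SimulatedDataset, SimulationConfig, simulate_all

logger = logging.getLogger("gutreg")

GENE_CONTRASTS = (
    ("WTCV/WTGF", ("WT", "CV"), ("WT", "GF")),
    ("MutCV/MutGF", ("Mut", "CV"), ("Mut", "GF")),
    ("WTCV/MutCV", ("WT", "CV"), ("Mut", "CV")),
    ("WTGF/MutGF", ("WT", "GF"), ("Mut", "GF")),
)


@dataclass
class Thresholds:
    q_gene: float = 0.05
    q_region: float = 0.01
    max_distance: int = 10_000
    flank: int = 1_000
    bin_width: int = 50
    delta: float = 1.0

    def __post_init__(self):
        for name in dataclasses.fields(self):
            if getattr(self, name.name) <= 0:
                raise ValueError(f"threshold {name.name} must be positive")


@dataclass
class PipelineConfig:
    """Either a simulate block or a dataset directory, plus thresholds."""

    simulate: SimulationConfig | None = None
    dataset: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulate is None) == (self.dataset is None):
            raise ValueError(
                "exactly one of a simulate block or a dataset path is required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulate")
        return cls(
            simulate=SimulationConfig(**_tupled(sim)) if sim is not None else None,
            dataset=raw.get("dataset"),
            thresholds=Thresholds(**raw.get("thresholds", {})),
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir"),
            log_level=raw.get("log_level", "INFO"),
        )

    def hash(self) -> str:
        payload = {
            "simulate": dataclasses.asdict(self.simulate) if self.simulate else None,
            "dataset": self.dataset,
            "thresholds": dataclasses.asdict(self.thresholds),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tupled(d: dict) -> dict:
    """YAML lists -> tuples for config fields that expect tuples."""
    out = dict(d)
    for key in ("base_mean_log_range", "library_factor_range", "peak_width"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


@dataclass
class PipelineReport:
    data: dict
    comparisons: dict[str, ExpressionComparison] | None = None
    labels: pd.Series | None = None
    dataset: SimulatedDataset | None = None

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")


def load_dataset(path: str | Path) -> SimulatedDataset:
    """Load a dataset directory laid out like :func:`simulate.write_dataset`."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {path}")
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    annotation = read_gene_annotation(path / "annotation.tsv")
    design = read_design(path / "design.tsv")
    counts = read_counts(path / "counts.tsv", design)
    peaks_gf = PeakSet("GF", read_bed(path / "peaks_GF.bed"))
    peaks_cv = PeakSet("CV", read_bed(path / "peaks_CV.bed"))
    track_gf = read_bedgraph(
        path / "coverage_GF.bedgraph", manifest["library_size_GF"]
    )
    track_cv = read_bedgraph(
        path / "coverage_CV.bedgraph", manifest["library_size_CV"]
    )
    region_design = read_design(path / "region_design.tsv")
    region_counts = read_counts(path / "region_counts.tsv", region_design)
    union = {r.name: r for r in peaks_gf.regions}
    union.update({r.name: r for r in peaks_cv.regions})
    hm = read_ortholog_table(path / "orthologs_human_mouse.tsv")
    mz = read_ortholog_table(path / "orthologs_mouse_zebrafish.tsv")
    disease = DiseaseGeneSet(
        manifest.get("disease_label", "disease"),
        read_disease_table(path / "disease.tsv"),
    )
    return SimulatedDataset(
        config=None, annotation=annotation, counts=counts, truth=None,
        peaks_gf=peaks_gf, peaks_cv=peaks_cv, track_gf=track_gf,
        track_cv=track_cv, region_counts=region_counts, union_regions=union,
        orthologs_hm=hm, orthologs_mz=mz, disease=disease,
    )


def run_pipeline(config: PipelineConfig, write: bool = False) -> PipelineReport:
    """Execute all stages; optionally write intermediates and report.json."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir) if config.outdir else None
    if write:
        if outdir is None:
            raise ValueError("writing requires an output directory")
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_config = config.simulate.replace(seed=config.seed)
            data = simulate_all(sim_config)
        else:
            stage = "load"
            data = load_dataset(config.dataset)
        th = config.thresholds

        stage = "diffexp"
        logger.info("differential expression over %d genes", len(data.counts.gene_ids))
        comparisons: dict[str, ExpressionComparison] = {}
        for label, num_cell, den_cell in GENE_CONTRASTS:
            comparisons[label] = differential_table(
                data.counts,
                data.counts.cell_samples(*num_cell),
                data.counts.cell_samples(*den_cell),
                label=label,
                q_threshold=th.q_gene,
            )

        stage = "four_way"
        membership = classify_four_way(comparisons, th.q_gene)

        stage = "quadrants"
        # x axis is GF over CV within WT (the reverse of the computed
        # WTCV/WTGF contrast); y axis is WT over Mut within CV as computed.
        labels = quadrant_labels(
            comparisons["WTCV/WTGF"],
            comparisons["WTCV/MutCV"],
            q_threshold=th.q_gene,
            flip_x=True,
        )
        summary = coregulation_summary(labels)

        stage = "diffregion"
        reg_cm = data.region_counts
        reg_comp = differential_table(
            reg_cm,
            reg_cm.cell_samples("WT", "GF"),
            reg_cm.cell_samples("WT", "CV"),
            label="GF/CV",
            q_threshold=th.q_region,
        )
        t = reg_comp.table
        gf_names = list(t.index[(t["significant"]) & (t["log2fc"] > 0)])
        cv_names = list(t.index[(t["significant"]) & (t["log2fc"] < 0)])
        gf_enriched = PeakSet(
            "GF-enriched", [data.union_regions[n] for n in gf_names]
        )
        cv_enriched = PeakSet(
            "CV-enriched", [data.union_regions[n] for n in cv_names]
        )

        stage = "associate"
        assign_gf_enriched = assign_peaks_to_genes(
            gf_enriched, data.annotation, th.max_distance
        )
        assign_cv_enriched = assign_peaks_to_genes(
            cv_enriched, data.annotation, th.max_distance
        )
        assign_gf_all = assign_peaks_to_genes(
            data.peaks_gf, data.annotation, th.max_distance
        )
        assign_cv_all = assign_peaks_to_genes(
            data.peaks_cv, data.annotation, th.max_distance
        )

        stage = "concord"
        ks = ks_region_expression(
            assign_cv_enriched, assign_gf_enriched, comparisons["WTCV/WTGF"]
        )

        stage = "compare_peaks"
        peak_cmp = compare_peak_sets(data.peaks_gf, data.peaks_cv)

        stage = "profile"
        prof_gf = flanking_signal_matrix(
            data.peaks_gf, data.track_gf, th.flank, th.bin_width
        )
        prof_cv = flanking_signal_matrix(
            data.peaks_gf, data.track_cv, th.flank, th.bin_width
        )
        mean_gf, _ = mean_profile(prof_gf)
        mean_cv, _ = mean_profile(prof_cv)
        center = prof_gf.n_bins // 2

        stage = "orthologs"
        map_hm = one_to_one_filter(data.orthologs_hm, "human", "mouse")
        map_mz = one_to_one_filter(data.orthologs_mz, "mouse", "zebrafish")
        chain = chain_orthologs(map_hm, map_mz)
        human_to_fish = chain.a_to_c()
        fish_to_human = chain.c_to_a()

        stage = "enrich"
        expr_y = comparisons["WTCV/MutCV"]
        tested = set(expr_y.table.index[expr_y.table["tested"]])
        universe = set(chain.triples["gene_c"]) & tested
        annotated = {
            "GF": assign_gf_all.assigned_genes & universe,
            "CV": assign_cv_all.assigned_genes & universe,
        }
        queries = {}
        for direction in ("down", "up"):
            mapped = {
                human_to_fish[g]
                for g in data.disease.genes(direction)
                if g in human_to_fish
            }
            queries[f"{data.disease.disease_label}_{direction}"] = mapped
        enrich = enrichment_table(queries, annotated, universe)
        proportions = pd.concat(
            [
                association_proportions(
                    data.disease, assign_gf_all.assigned_genes, human_to_fish
                ).assign(condition="GF"),
                association_proportions(
                    data.disease, assign_cv_all.assigned_genes, human_to_fish
                ).assign(condition="CV"),
            ],
            ignore_index=True,
        )

        stage = "deming"
        fc = {
            label: comparisons[label].fold_changes(tested_only=True)
            for label, _, _ in GENE_CONTRASTS
        }
        axes = {
            "WTCV/WTGF": fc["WTCV/WTGF"].to_dict(),
            "MutCV/MutGF": fc["MutCV/MutGF"].to_dict(),
            "MutCV/WTCV": (-fc["WTCV/MutCV"]).to_dict(),
            "MutGF/WTGF": (-fc["WTGF/MutGF"]).to_dict(),
        }
        bound = assign_gf_all.assigned_genes
        pair_sets = {}
        for label, fcs in axes.items():
            pair_sets[label] = build_pairs(
                fcs, data.disease, gene_map=fish_to_human,
                label_x=label, label_y=data.disease.disease_label,
            )
        for tag, restrict in (
            ("bound", bound),
            ("unbound", set(fc["WTCV/MutCV"].index) - bound),
        ):
            try:
                pair_sets[f"MutCV/WTCV[{tag}]"] = build_pairs(
                    axes["MutCV/WTCV"], data.disease, gene_map=fish_to_human,
                    restrict_to=restrict,
                    label_x=f"MutCV/WTCV[{tag}]",
                    label_y=data.disease.disease_label,
                )
            except Exception:  # too few pairs in a split is not fatal
                logger.warning("skipping Deming split %s: too few pairs", tag)
        fits, tests = concordance_grid(
            pair_sets, reference="WTCV/WTGF", delta=th.delta
        )

        stage = "report"
        report = {
            "provenance": {
                "config_hash": config.hash(),
                "seed": config.seed,
                "version": __version__,
            },
            "differential": {
                label: {
                    "n_significant": int(len(c.significant_genes)),
                    "n_tested": int(c.table["tested"].sum()),
                }
                for label, c in comparisons.items()
            },
            "four_way": {
                "union": membership.union_size,
                "venn": membership.venn_counts(),
            },
            "coregulation": summary.as_dict(),
            "region_differential": {
                "n_gf_enriched": len(gf_names),
                "n_cv_enriched": len(cv_names),
                "n_regions": len(reg_cm.gene_ids),
            },
            "ks_concordance": {
                **ks.ks.as_dict(),
                "n_cv_genes": ks.n_cv_genes,
                "n_gf_genes": ks.n_gf_genes,
                "n_in_both": ks.n_in_both,
                "mode": ks.mode,
            },
            "peak_comparison": {
                "label_a": peak_cmp.label_a,
                "label_b": peak_cmp.label_b,
                **peak_cmp.counts(),
            },
            "profiles": {
                "gf_mean": mean_gf.tolist(),
                "cv_mean": mean_cv.tolist(),
                "gf_center": float(mean_gf[center]),
                "cv_center": float(mean_cv[center]),
            },
            "orthologs": {
                "n_one_to_one_hm": len(map_hm),
                "n_one_to_one_mz": len(map_mz),
                "n_chained": len(chain),
            },
            "enrichment": enrich.to_dict(orient="records"),
            "association_proportions": proportions.to_dict(orient="records"),
            "deming": {
                "fits": fits.to_dict(orient="records"),
                "tests": tests.to_dict(orient="records"),
            },
        }
        result = PipelineReport(report, comparisons, labels, data)

        if write:
            stage = "write"
            for label, comp in comparisons.items():
                safe = label.replace("/", "_vs_")
                write_differential_table(comp, outdir / f"diffexp_{safe}.tsv")
            write_differential_table(reg_comp, outdir / "diffregion_GF_vs_CV.tsv")
            labels.to_frame().to_csv(outdir / "gene_classes.tsv", sep="\t")
            write_assignment(assign_gf_all, outdir / "assignment_GF.tsv")
            write_assignment(assign_cv_all, outdir / "assignment_CV.tsv")
            write_profile_matrix(prof_gf, outdir / "profile_GF.tsv")
            write_profile_matrix(prof_cv, outdir / "profile_CV.tsv")
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            proportions.to_csv(outdir / "proportions.tsv", sep="\t", index=False)
            fits.to_csv(outdir / "deming_fits.tsv", sep="\t", index=False)
            tests.to_csv(outdir / "deming_tests.tsv", sep="\t", index=False)
            with open(outdir / "report.json", "w") as fh:
                fh.write(result.to_json())
        return result
    except StageError:
        raise
    except Exception as exc:
        if write and outdir is not None:
            (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise StageError(stage, exc) from exc
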