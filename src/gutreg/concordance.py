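"""Integration statistics linking differential expression, genotype and
enhancer state.

Three layers:

* four-way membership logic over the WTCV/WTGF, MutCV/MutGF, WTCV/MutCV and
  WTGF/MutGF contrasts (union and all 15 Venn region counts);
* fold-change quadrant classification of genes significant on both the
  microbiota axis (GF vs CV within WT) and the genotype axis (WT vs Mut
  within CV) into suppressed/induced x activated/repressed classes;
* a two-sample Kolmogorov-Smirnov test relating condition-enriched
  regulatory regions to the expression direction of their assigned genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .diffcount import ExpressionComparison
from .errors import DegenerateDataError
from .regions import PeakGeneAssignment

QUADRANT_LABELS = (
    "suppressed_activated",
    "suppressed_repressed",
    "induced_activated",
    "induced_repressed",
    "not_coregulated",
)


@dataclass
class FourWayMembership:
    """Per-gene significance flags over four contrasts plus Venn counts."""

    flags: pd.DataFrame  # genes x 4 bool
    q_threshold: float

    @property
    def union_size(self) -> int:
        return int(self.flags.any(axis=1).sum())

    @property
    def union_genes(self) -> set[str]:
        return set(self.flags.index[self.flags.any(axis=1)])

    def venn_counts(self) -> dict[str, int]:
        """Counts of the 15 disjoint non-empty Venn regions.

        Keys are '&'-joined contrast labels in column order; each gene is
        counted in exactly the region matching its flag pattern.
        """
        labels = list(self.flags.columns)
        counts: dict[str, int] = {}
        arr = self.flags.to_numpy()
        for r in range(1, len(labels) + 1):
            for combo in itertools.combinations(range(len(labels)), r):
                pattern = np.zeros(len(labels), dtype=bool)
                pattern[list(combo)] = True
                key = "&".join(labels[i] for i in combo)
                counts[key] = int(np.all(arr == pattern, axis=1).sum())
        assert sum(counts.values()) == self.union_size  # partition identity
        return counts

    def pairwise_intersection(self, a: str, b: str) -> int:
        return int((self.flags[a] & self.flags[b]).sum())


@dataclass
class KsResult:
    D: float
    p: float
    n1: int
    n2: int
    shift_sign: int

    def as_dict(self) -> dict:
        return {
            "D": self.D,
            "p": self.p,
            "n1": self.n1,
            "n2": self.n2,
            "shift_sign": self.shift_sign,
        }


@dataclass
class RegionExpressionKs:
    """KS comparison of expression fold changes by enhancer condition."""

    ks: KsResult
    n_cv_genes: int
    n_gf_genes: int
    n_in_both: int
    mode: str


def classify_four_way(
    comparisons: dict[str, ExpressionComparison], q_threshold: float = 0.05
) -> FourWayMembership:
    """Significance flags q < threshold per gene per contrast.

    All comparisons must cover the same gene universe; untested genes are
    never flagged.
    """
    labels = list(comparisons)
    universe = None
    cols = {}
    for label in labels:
        comp = comparisons[label]
        idx = comp.table.index
        if universe is None:
            universe = idx
        elif not universe.equals(idx):
            raise ValueError(
                f"comparison {label!r} covers a different gene universe"
            )
        q = comp.table["q"].to_numpy()
        cols[label] = np.where(np.isfinite(q), q < q_threshold, False)
    flags = pd.DataFrame(cols, index=universe)
    return FourWayMembership(flags, q_threshold)


def quadrant_classify(
    fc_x: float, q_x: float, fc_y: float, q_y: float, q_threshold: float = 0.05
) -> str:
    """Classify one gene by its (microbiota, genotype) fold-change signs.

    x axis: log2FC of GF over CV within WT (positive = microbiota-
    suppressed); y axis: log2FC of WT over Mut within CV (positive =
    activated by the TF).  Genes not significant on both axes are
    not_coregulated; a significant axis with exactly zero fold change is
    contradictory input.
    """
    if not (np.isfinite(fc_x) and np.isfinite(fc_y)):
        raise ValueError("fold changes must be finite")
    if not (np.isfinite(q_x) and q_x < q_threshold) or not (
        np.isfinite(q_y) and q_y < q_threshold
    ):
        return "not_coregulated"
    if fc_x == 0 or fc_y == 0:
        raise DegenerateDataError(
            "zero fold change with a significant q-value is contradictory"
        )
    if fc_x > 0:
        return "suppressed_activated" if fc_y > 0 else "suppressed_repressed"
    return "induced_activated" if fc_y > 0 else "induced_repressed"


def quadrant_labels(
    comp_x: ExpressionComparison,
    comp_y: ExpressionComparison,
    q_threshold: float = 0.05,
    flip_x: bool = False,
    flip_y: bool = False,
) -> pd.Series:
    """Vectorized quadrant classification over a shared gene universe.

    ``flip_x``/``flip_y`` negate the stored fold change when the desired
    axis direction is the reverse of the computed contrast (the sign flip
    is exact under numerator/denominator swap).
    """
    if not comp_x.table.index.equals(comp_y.table.index):
        raise ValueError("comparisons cover different gene universes")
    sx = -1.0 if flip_x else 1.0
    sy = -1.0 if flip_y else 1.0
    labels = pd.Series("not_coregulated", index=comp_x.table.index, name="class")
    qx = comp_x.table["q"].to_numpy()
    qy = comp_y.table["q"].to_numpy()
    sig = (
        np.isfinite(qx) & (qx < q_threshold) & np.isfinite(qy) & (qy < q_threshold)
    )
    fx = sx * comp_x.table["log2fc"].to_numpy()
    fy = sy * comp_y.table["log2fc"].to_numpy()
    if np.any(sig & ((fx == 0) | (fy == 0))):
        raise DegenerateDataError(
            "zero fold change with a significant q-value is contradictory"
        )
    labels[sig & (fx > 0) & (fy > 0)] = "suppressed_activated"
    labels[sig & (fx > 0) & (fy < 0)] = "suppressed_repressed"
    labels[sig & (fx < 0) & (fy > 0)] = "induced_activated"
    labels[sig & (fx < 0) & (fy < 0)] = "induced_repressed"
    return labels


@dataclass
class CoregulationSummary:
    n_shared: int
    class_counts: dict[str, int]
    suppressed_activated_fraction: float | None

    def as_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "class_counts": self.class_counts,
            "suppressed_activated_fraction": self.suppressed_activated_fraction,
        }


def coregulation_summary(labels: pd.Series) -> CoregulationSummary:
    """Counts per quadrant class and the suppressed-side activated fraction.

    The fraction is suppressed_activated / (suppressed_activated +
    suppressed_repressed), i.e. the share of microbiota-suppressed
    coregulated genes that the TF activates; None when no gene is
    microbiota-suppressed.
    """
    counts = {lab: int((labels == lab).sum()) for lab in QUADRANT_LABELS}
    n_shared = int((labels != "not_coregulated").sum())
    n_sup = counts["suppressed_activated"] + counts["suppressed_repressed"]
    fraction = counts["suppressed_activated"] / n_sup if n_sup else None
    return CoregulationSummary(n_shared, counts, fraction)


def _ecdf_values(sample: np.ndarray, at: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(sample), at, side="right") / sample.size


def ks_two_sample(x, y, mode: str = "asymp") -> KsResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute ECDF difference over all pooled points.  The
    p-value comes from the asymptotic Kolmogorov distribution evaluated at
    sqrt(n1*n2/(n1+n2)) * D; ``mode='exact'`` uses the exact small-sample
    distribution instead (intended for n1*n2 <= 1e4).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("asymp", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    D = float(np.max(np.abs(_ecdf_values(x, pooled) - _ecdf_values(y, pooled))))
    if mode == "exact":
        p = float(stats.ks_2samp(x, y, method="exact").pvalue)
    else:
        en = x.size * y.size / (x.size + y.size)
        p = float(special.kolmogorov(np.sqrt(en) * D))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    shift = float(np.mean(x) - np.mean(y))
    return KsResult(D, p, int(x.size), int(y.size), int(np.sign(shift)))


def ks_region_expression(
    cv_assignment: PeakGeneAssignment,
    gf_assignment: PeakGeneAssignment,
    expression: ExpressionComparison,
    mode: str = "asymp",
    against_background: bool = False,
) -> RegionExpressionKs:
    """KS test of CV/GF expression fold changes by enhancer condition.

    Sample A holds the log2FC (CV over GF) of genes assigned to CV-enriched
    regions, sample B the same for GF-enriched regions; genes assigned to
    both kinds of region contribute to both samples.  A positive shift sign
    means genes near CV-gained enhancers are more highly expressed after
    colonization.  With ``against_background=True`` each group is instead
    compared against all tested genes and the larger-D comparison is
    reported.
    """
    fc = expression.fold_changes(tested_only=True)
    genes_cv = cv_assignment.assigned_genes & set(fc.index)
    genes_gf = gf_assignment.assigned_genes & set(fc.index)
    if not genes_cv:
        raise DegenerateDataError("no CV-enriched region maps to a tested gene")
    if not genes_gf:
        raise DegenerateDataError("no GF-enriched region maps to a tested gene")
    a = fc.loc[sorted(genes_cv)].to_numpy()
    b = fc.loc[sorted(genes_gf)].to_numpy()
    if against_background:
        background = fc.to_numpy()
        ks_a = ks_two_sample(a, background, mode=mode)
        ks_b = ks_two_sample(b, background, mode=mode)
        ks = ks_a if ks_a.D >= ks_b.D else ks_b
        used = "background"
    else:
        ks = ks_two_sample(a, b, mode=mode)
        used = "pairwise"
    return RegionExpressionKs(
        ks, len(genes_cv), len(genes_gf), len(genes_cv & genes_gf), used
    )
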