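"""Errors-in-variables (Deming) regression of paired log2 fold changes.

When both axes carry experimental noise, ordinary least squares attenuates
the slope toward zero; Deming regression instead minimizes perpendicular
(variance-weighted) distances and is consistent for the structural slope.
With delta = sigma_y^2 / sigma_x^2 the closed-form slope is

    m = (s_yy - delta*s_xx + sqrt((s_yy - delta*s_xx)^2 + 4*delta*s_xy^2))
        / (2 * s_xy)

and the intercept is ybar - m * xbar.  The slope standard error comes from
a leave-one-out jackknife, and slopes of two independent fits are compared
with a normal z test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffcount import ExpressionComparison, bh_adjust
from .errors import DegenerateDataError
from .orthologs import DiseaseGeneSet


@dataclass
class PairedFoldChanges:
    """Paired (x, y) log2 fold changes for ortholog-linked genes."""

    x: np.ndarray
    y: np.ndarray
    label_x: str
    label_y: str
    gene_ids: list[str] | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("fold changes must be finite")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class DemingFit:
    slope: float
    intercept: float
    delta: float
    se_slope: float
    ci95: tuple[float, float]
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "delta": self.delta,
            "se_slope": self.se_slope,
            "ci95": list(self.ci95),
            "n": self.n,
        }


@dataclass
class SlopeTest:
    z: float
    p: float
    alternative: str
    degenerate: bool = False


def fold_change_map(obj) -> dict[str, float]:
    """Gene -> log2FC mapping from a comparison or disease list."""
    if isinstance(obj, ExpressionComparison):
        return obj.fold_changes(tested_only=True).to_dict()
    if isinstance(obj, DiseaseGeneSet):
        return dict(zip(obj.table["gene"], obj.table["log2fc"]))
    if isinstance(obj, Mapping):
        return dict(obj)
    raise TypeError(f"cannot extract fold changes from {type(obj).__name__}")


def build_pairs(
    a,
    b,
    gene_map: Mapping[str, str] | None = None,
    restrict_to: set[str] | None = None,
    label_x: str = "x",
    label_y: str = "y",
) -> PairedFoldChanges:
    """Pair fold changes of ``a`` (x axis) and ``b`` (y axis) via orthology.

    ``gene_map`` translates a's gene ids into b's namespace (identity when
    None); ``restrict_to`` optionally keeps only a-genes in a given set
    (e.g. genes with / without a binding association).  Fewer than 3
    surviving pairs is an error.
    """
    fa = fold_change_map(a)
    fb = fold_change_map(b)
    xs, ys, genes = [], [], []
    for gene_a, x in fa.items():
        if restrict_to is not None and gene_a not in restrict_to:
            continue
        gene_b = gene_map.get(gene_a) if gene_map is not None else gene_a
        if gene_b is None or gene_b not in fb:
            continue
        if not (np.isfinite(x) and np.isfinite(fb[gene_b])):
            continue
        xs.append(x)
        ys.append(fb[gene_b])
        genes.append(gene_a)
    if len(xs) < 3:
        raise DegenerateDataError(
            f"only {len(xs)} ortholog-linked pairs survive; >= 3 required"
        )
    return PairedFoldChanges(np.array(xs), np.array(ys), label_x, label_y, genes)


def _deming_slope(s_xx, s_yy, s_xy, delta: float):
    """Closed-form Deming slope; NaN marks a degenerate orientation."""
    s_xx = np.asarray(s_xx, dtype=float)
    s_yy = np.asarray(s_yy, dtype=float)
    s_xy = np.asarray(s_xy, dtype=float)
    diff = s_yy - delta * s_xx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (diff + np.sqrt(diff**2 + 4.0 * delta * s_xy**2)) / (2.0 * s_xy)
    # s_xy == 0: horizontal best line when x dominates, degenerate otherwise
    slope = np.where(s_xy == 0, np.where(diff < 0, 0.0, np.nan), slope)
    return slope


def deming_fit(points: PairedFoldChanges, delta: float = 1.0) -> DemingFit:
    """Deming fit with leave-one-out jackknife slope standard error.

    ``delta`` is the assumed error-variance ratio sigma_y^2/sigma_x^2
    (1 when both axes are equally noisy, the default for log2FC pairs).
    For delta = 1 the fit is symmetric: swapping axes yields the
    reciprocal slope.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    x, y, n = points.x, points.y, points.n
    if n < 3:
        raise DegenerateDataError(f"need >= 3 points, got {n}")
    s_xx = np.var(x, ddof=1)
    s_yy = np.var(y, ddof=1)
    s_xy = np.cov(x, y, ddof=1)[0, 1]
    slope = float(_deming_slope(s_xx, s_yy, s_xy, delta))
    if not np.isfinite(slope):
        raise DegenerateDataError(
            "degenerate orientation: zero covariance with s_yy >= delta*s_xx"
        )
    intercept = float(np.mean(y) - slope * np.mean(x))

    # Vectorized leave-one-out second moments via downdating.
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    lo_sx, lo_sy = sx - x, sy - y
    lo_sxx = (sxx - x * x - lo_sx**2 / m) / (m - 1)
    lo_syy = (syy - y * y - lo_sy**2 / m) / (m - 1)
    lo_sxy = (sxy - x * y - lo_sx * lo_sy / m) / (m - 1)
    lo_slopes = _deming_slope(lo_sxx, lo_syy, lo_sxy, delta)
    if not np.all(np.isfinite(lo_slopes)):
        raise DegenerateDataError(
            "jackknife replicate hit a degenerate orientation"
        )
    se = float(np.sqrt((n - 1) / n * np.sum((lo_slopes - lo_slopes.mean()) ** 2)))
    ci = (slope - 1.96 * se, slope + 1.96 * se)
    return DemingFit(slope, intercept, delta, se, ci, n)


def deming_objective(points: PairedFoldChanges, slope: float, delta: float = 1.0):
    """Profile objective minimized by the Deming slope (for oracle checks).

    For a given slope b with optimal intercept ybar - b*xbar, the summed
    weighted squared perpendicular distances are
    sum (y - a - b*x)^2 / (delta + b^2), up to the fixed sigma_x^2 scale.
    """
    a = np.mean(points.y) - slope * np.mean(points.x)
    resid = points.y - a - slope * points.x
    return float(np.sum(resid**2) / (delta + slope**2))


def slope_difference_test(
    fit1: DemingFit, fit2: DemingFit, alternative: str = "greater"
) -> SlopeTest:
    """Normal z test of slope(fit1) - slope(fit2).

    One-sided 'greater' tests whether fit1's slope exceeds fit2's (the
    default); 'two_sided' doubles the tail.  Two exact fits with equal
    slopes give z = 0; unequal exact fits are reported as p = 0 with a
    degeneracy flag.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    se = np.hypot(fit1.se_slope, fit2.se_slope)
    if se == 0:
        if fit1.slope == fit2.slope:
            z = 0.0
        else:
            return SlopeTest(
                np.inf if fit1.slope > fit2.slope else -np.inf,
                0.0,
                alternative,
                degenerate=True,
            )
    else:
        z = float((fit1.slope - fit2.slope) / se)
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return SlopeTest(z, min(p, 1.0), alternative)


def concordance_grid(
    pairs_sets: dict[str, PairedFoldChanges],
    reference: str | None = None,
    delta: float = 1.0,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deming slopes for labeled pair sets plus tests against a reference.

    Returns (fits, tests): ``fits`` has one row per label with slope, se,
    ci and n; ``tests`` compares every non-reference cell against the
    reference cell (empty when no reference or a single cell), with BH
    adjustment across the tested cells.
    """
    if not pairs_sets:
        raise ValueError("need at least one pair set")
    fits = {label: deming_fit(ps, delta=delta) for label, ps in pairs_sets.items()}
    fit_rows = [
        {
            "label": label,
            "slope": f.slope,
            "intercept": f.intercept,
            "se_slope": f.se_slope,
            "ci_low": f.ci95[0],
            "ci_high": f.ci95[1],
            "n": f.n,
        }
        for label, f in fits.items()
    ]
    test_rows = []
    if reference is not None and len(fits) > 1:
        if reference not in fits:
            raise KeyError(f"reference {reference!r} not among pair sets")
        for label, f in fits.items():
            if label == reference:
                continue
            t = slope_difference_test(f, fits[reference], alternative=alternative)
            test_rows.append(
                {"label": label, "reference": reference, "z": t.z, "p": t.p,
                 "degenerate": t.degenerate}
            )
    tests = pd.DataFrame(
        test_rows, columns=["label", "reference", "z", "p", "degenerate"]
    )
    if len(tests):
        tests["q"] = bh_adjust(tests["p"].to_numpy())
    return pd.DataFrame(fit_rows), tests
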