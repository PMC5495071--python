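"""Genomic-interval computations: peak-to-gene assignment, peak-set
comparison across conditions, and flanking-signal profile matrices.

The reference point of a peak is its summit when recorded and the integer
midpoint otherwise; distances are measured to gene TSSs only (not gene
bodies).  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import GeneRecord, GenomicRegion, SignalTrack

DEFAULT_MAX_DISTANCE = 10_000
DEFAULT_FLANK = 1_000
DEFAULT_BIN_WIDTH = 50


@dataclass
class PeakSet:
    """A labeled collection of genomic regions (e.g. a TF cistrome in GF)."""

    condition_label: str
    regions: list[GenomicRegion]

    def __post_init__(self):
        if not self.condition_label:
            raise ValueError("condition_label must be non-empty")

    def __len__(self) -> int:
        return len(self.regions)

    def names(self) -> list[str]:
        return [
            r.name if r.name is not None else f"{r.chrom}:{r.start}-{r.end}"
            for r in self.regions
        ]


@dataclass
class PeakGeneAssignment:
    """Per-peak single-nearest-TSS assignment within a distance cutoff.

    ``table`` has one row per peak: peak_name, gene_id (None when
    unassigned) and distance (|reference - TSS| in bp, NaN when unassigned).
    """

    table: pd.DataFrame
    max_distance: int

    @property
    def assigned_genes(self) -> set[str]:
        return set(self.table["gene_id"].dropna())

    def genes_for_peaks(self) -> pd.Series:
        return self.table.set_index("peak_name")["gene_id"]


@dataclass
class PeakComparison:
    """Partition of two peak sets into shared and condition-unique regions."""

    label_a: str
    label_b: str
    shared_a: list[GenomicRegion]
    unique_a: list[GenomicRegion]
    shared_b: list[GenomicRegion]
    unique_b: list[GenomicRegion]

    def counts(self) -> dict[str, int]:
        return {
            "shared_a": len(self.shared_a),
            "unique_a": len(self.unique_a),
            "shared_b": len(self.shared_b),
            "unique_b": len(self.unique_b),
        }


@dataclass
class ProfileMatrix:
    """Normalized signal per site x bin over [-flank, +flank) around summits.

    ``values`` is sites x bins; ``truncated`` flags bins that fell before
    the chromosome start and were zero-filled.  Values are per-base signal
    normalized RPKM-style by bin width (kb) and library size (millions);
    the normalization constant is recorded so profiles from different
    tracks are comparable.
    """

    site_ids: list[str]
    values: np.ndarray
    truncated: np.ndarray
    flank: int
    bin_width: int
    normalization_constant: float

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_centers(self) -> np.ndarray:
        edges = np.arange(-self.flank, self.flank + 1, self.bin_width)
        return (edges[:-1] + edges[1:]) / 2.0


def _annotation_index(annotation: Sequence[GeneRecord]):
    """Per-chromosome (tss sorted, gene_id aligned) arrays for fast lookup."""
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in annotation:
        per_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    out = {}
    for chrom, items in per_chrom.items():
        items.sort()
        tss = np.array([t for t, _ in items], dtype=np.int64)
        ids = np.array([i for _, i in items], dtype=object)
        out[chrom] = (tss, ids)
    return out


def assign_peaks_to_genes(
    peaks: PeakSet,
    annotation: Sequence[GeneRecord],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> PeakGeneAssignment:
    """Assign each peak to the single nearest gene TSS within ``max_distance``.

    The reference point is the summit when present, else the midpoint.
    Only genes on the same chromosome are candidates; ties in distance are
    broken by the lexicographically smaller gene_id.  Peaks on chromosomes
    absent from the annotation are left unassigned.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    index = _annotation_index(annotation)
    rows = []
    for name, region in zip(peaks.names(), peaks.regions):
        ref = region.reference_point
        gene, dist = None, math.nan
        if region.chrom in index:
            tss, ids = index[region.chrom]
            pos = int(np.searchsorted(tss, ref))
            best = None
            if pos > 0:
                best = int(ref - tss[pos - 1])
            if pos < len(tss):
                d = int(tss[pos] - ref)
                best = d if best is None else min(best, d)
            if best is not None and best <= max_distance:
                candidates = []
                for target in (ref - best, ref + best):
                    lo = int(np.searchsorted(tss, target, side="left"))
                    hi = int(np.searchsorted(tss, target, side="right"))
                    candidates.extend(ids[lo:hi])
                gene = min(candidates)
                dist = float(best)
        rows.append((name, gene, dist))
    table = pd.DataFrame(rows, columns=["peak_name", "gene_id", "distance"])
    return PeakGeneAssignment(table, max_distance)


def _overlap_mask(
    regions_a: list[GenomicRegion], regions_b: list[GenomicRegion], min_overlap: int
) -> np.ndarray:
    """Boolean per region in A: overlaps >= min_overlap bp with any of B."""
    by_chrom_b: dict[str, list[GenomicRegion]] = {}
    for r in regions_b:
        by_chrom_b.setdefault(r.chrom, []).append(r)
    mask = np.zeros(len(regions_a), dtype=bool)
    arrays = {
        chrom: (
            np.array([r.start for r in rs], dtype=np.int64),
            np.array([r.end for r in rs], dtype=np.int64),
        )
        for chrom, rs in by_chrom_b.items()
    }
    for i, r in enumerate(regions_a):
        arr = arrays.get(r.chrom)
        if arr is None:
            continue
        starts, ends = arr
        overlap = np.minimum(r.end, ends) - np.maximum(r.start, starts)
        mask[i] = bool(np.any(overlap >= min_overlap))
    return mask


def compare_peak_sets(
    a: PeakSet, b: PeakSet, min_overlap: int = 1
) -> PeakComparison:
    """Partition each peak set into regions shared with / unique to the other.

    A region of A is shared iff it overlaps at least ``min_overlap`` bp
    (half-open overlap) with at least one region of B, and symmetrically.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    mask_a = _overlap_mask(a.regions, b.regions, min_overlap)
    mask_b = _overlap_mask(b.regions, a.regions, min_overlap)
    return PeakComparison(
        a.condition_label,
        b.condition_label,
        shared_a=[r for r, m in zip(a.regions, mask_a) if m],
        unique_a=[r for r, m in zip(a.regions, mask_a) if not m],
        shared_b=[r for r, m in zip(b.regions, mask_b) if m],
        unique_b=[r for r, m in zip(b.regions, mask_b) if not m],
    )


def count_overlapping_pairs(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> int:
    """Number of (region_a, region_b) pairs overlapping >= min_overlap bp."""
    total = 0
    by_chrom_b: dict[str, list[GenomicRegion]] = {}
    for r in b.regions:
        by_chrom_b.setdefault(r.chrom, []).append(r)
    for r in a.regions:
        for rb in by_chrom_b.get(r.chrom, []):
            if min(r.end, rb.end) - max(r.start, rb.start) >= min_overlap:
                total += 1
    return total


def flanking_signal_matrix(
    sites: PeakSet,
    track: SignalTrack,
    flank: int = DEFAULT_FLANK,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> ProfileMatrix:
    """Binned, RPKM-normalized signal in [-flank, +flank) around each summit.

    value(site, bin) = (per-base coverage sum over the bin)
                       / ((bin_width/1000) * (library_size/1e6)).

    Bins truncated at the chromosome start are zero-filled and flagged in
    ``truncated``; positions beyond the recorded track are coverage 0 by
    bedGraph semantics.
    """
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    if (2 * flank) % bin_width != 0:
        raise ValueError(
            f"bin_width {bin_width} must divide the window width {2 * flank}"
        )
    n_bins = (2 * flank) // bin_width
    norm = (bin_width / 1000.0) * (track.library_size / 1e6)
    values = np.zeros((len(sites), n_bins))
    truncated = np.zeros((len(sites), n_bins), dtype=bool)
    offsets = np.arange(n_bins + 1) * bin_width - flank
    for i, region in enumerate(sites.regions):
        ref = region.reference_point
        edges = ref + offsets
        clipped = np.clip(edges, 0, None)
        mass = track.cumulative_mass(region.chrom, clipped)
        values[i] = np.diff(mass) / norm
        truncated[i] = edges[:-1] < 0
    values[truncated] = 0.0
    return ProfileMatrix(sites.names(), values, truncated, flank, bin_width, norm)


def mean_profile(matrix: ProfileMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean over sites, excluding zero-filled truncated bins.

    Returns (means, n_contributing) arrays of length n_bins.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("profile matrix has no sites")
    contributing = ~matrix.truncated
    n = contributing.sum(axis=0)
    total = np.where(contributing, matrix.values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return means, n


def write_assignment(assignment: PeakGeneAssignment, path) -> None:
    out = assignment.table.copy()
    out["gene_id"] = out["gene_id"].fillna("NA")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_profile_matrix(matrix: ProfileMatrix, path) -> None:
    cols = [f"{int(c)}" for c in matrix.bin_centers()]
    df = pd.DataFrame(matrix.values, index=matrix.site_ids, columns=cols)
    df.index.name = "site_id"
    df.to_csv(path, sep="\t")
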