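"""Readers and writers for the flat-file formats the pipeline consumes.

Coordinate conventions are strict throughout the package: genomic intervals
are 0-based half-open (`[start, end)`, length ``end - start``), exactly as in
BED and bedGraph.  No 1-based dialect detection is attempted, and chromosome
names are compared as exact strings (no ``chr`` aliasing).

Supported formats:

* BED3/BED4/BED5 for peak and region sets, with an optional 7th column
  carrying the summit offset from the region start (narrowPeak-style
  point source);
* bedGraph for piecewise-constant coverage tracks;
* headered TSV for gene annotations, count matrices, sample designs,
  ortholog tables and disease gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

VALID_STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open, optionally with a summit.

    ``summit_offset`` is the offset of the point of maximal signal from
    ``start``; it must fall inside the interval.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside interval of "
                f"length {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def reference_point(self) -> int:
        """Summit position if recorded, else the integer midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to the fields the pipeline needs: id, strand, TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


class SignalTrack:
    """Piecewise-constant coverage with bedGraph semantics.

    Positions not covered by any interval have value 0.  Intervals within a
    chromosome are kept sorted and non-overlapping; values are >= 0.
    ``library_size`` is the total read count used for RPKM-style
    normalization and must be positive.
    """

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int, float]],
        library_size: float,
    ):
        if library_size <= 0:
            raise ValueError(f"library_size must be > 0, got {library_size}")
        self.library_size = float(library_size)
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if not (0 <= start < end):
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            if value < 0:
                raise ValueError(f"negative coverage {value} at {chrom}:{start}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            starts = np.array([i[0] for i in ivals], dtype=np.int64)
            ends = np.array([i[1] for i in ivals], dtype=np.int64)
            values = np.array([i[2] for i in ivals], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                bad = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise ValueError(
                    f"overlapping intervals on {chrom} near position "
                    f"{int(starts[bad + 1])}"
                )
            self._chroms[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def arrays(self, chrom: str):
        """(starts, ends, values) arrays for one chromosome, or None."""
        return self._chroms.get(chrom)

    def n_intervals(self) -> int:
        return sum(len(v[0]) for v in self._chroms.values())

    def cumulative_mass(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integral of coverage over (-inf, pos) for each position.

        Differences of this function give exact per-base sums over any
        window, which is how profile matrices are binned.
        """
        arr = self._chroms.get(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if arr is None:
            return np.zeros(positions.shape, dtype=float)
        starts, ends, values = arr
        cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
        idx = np.searchsorted(starts, positions, side="right") - 1
        idx_c = np.clip(idx, 0, len(starts) - 1)
        inside = np.clip(positions - starts[idx_c], 0, ends[idx_c] - starts[idx_c])
        mass = cum[idx_c] + values[idx_c] * inside
        return np.where(idx < 0, 0.0, mass)

    def total_mass(self) -> float:
        return float(
            sum(
                float(np.sum(v * (e - s)))
                for s, e, v in self._chroms.values()
            )
        )

    def iter_intervals(self):
        for chrom in self.chroms:
            starts, ends, values = self._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a BED3/4/5 file (optional 7th column = summit offset).

    Empty files yield an empty list.  Malformed coordinates raise
    :class:`FormatError` naming the line number.
    """
    regions: list[GenomicRegion] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            summit = None
            if len(fields) > 6 and fields[6] != ".":
                try:
                    summit = int(fields[6])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer summit") from exc
            try:
                regions.append(
                    GenomicRegion(fields[0], start, end, name, score, summit)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED, emitting only the columns that are populated.

    If any region carries a summit offset the file is BED6+1 with the summit
    in column 7 (strand column written as '.')."""
    any_summit = any(r.summit_offset is not None for r in regions)
    any_score = any(r.score is not None for r in regions) or any_summit
    any_name = any(r.name is not None for r in regions) or any_score
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.chrom, str(r.start), str(r.end)]
            if any_name:
                cols.append(r.name if r.name is not None else ".")
            if any_score:
                cols.append(repr(r.score) if r.score is not None else ".")
            if any_summit:
                cols.append(".")  # strand placeholder
                cols.append(
                    str(r.summit_offset) if r.summit_offset is not None else "."
                )
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation


def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a TSV with header columns gene_id, chrom, strand, tss."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: could not parse TSV: {exc}") from exc
    required = ["gene_id", "chrom", "strand", "tss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                GeneRecord(row.gene_id, row.chrom, row.strand, int(row.tss))
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
    return records


def write_gene_annotation(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def annotation_from_gtf_rows(
    rows: Iterable[tuple[str, str, int, int, str]]
) -> list[GeneRecord]:
    """Build GeneRecords from (gene_id, chrom, start, end, strand) gene rows
    with 1-based inclusive GTF coordinates.

    The TSS is the 5' end by strand: ``start - 1`` for '+' genes and
    ``end - 1`` for '-' genes, converted to 0-based.
    """
    out = []
    for gene_id, chrom, start, end, strand in rows:
        tss = start - 1 if strand == "+" else end - 1
        out.append(GeneRecord(gene_id, chrom, strand, tss))
    return out


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, library_size: float) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping intervals or negative values raise :class:`FormatError`;
    a non-positive ``library_size`` raises ``ValueError``.
    """
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    path = Path(path)
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed interval") from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            if not (0 <= start < end):
                raise FormatError(f"{path}:{lineno}: invalid coordinates")
            intervals.append((fields[0], start, end, value))
    try:
        return SignalTrack(intervals, library_size)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Count matrices and sample designs


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design TSV: sample, genotype, colonization, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = ["sample", "genotype", "colonization", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df.set_index("sample")


def read_counts(path: str | Path, design: pd.DataFrame | Mapping):
    """Read a genes x samples count TSV against a sample design.

    ``design`` maps sample name -> (genotype, colonization, replicate),
    either as a mapping or as a DataFrame indexed by sample.  Samples in
    the file and the design must match exactly; non-integer counts raise
    :class:`FormatError`.
    """
    from .diffcount import CountMatrix  # local import to avoid a cycle

    path = Path(path)
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame.from_dict(
            dict(design),
            orient="index",
            columns=["genotype", "colonization", "replicate"],
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    file_samples = list(df.columns)
    design_samples = list(design.index)
    extra = sorted(set(file_samples) - set(design_samples))
    if extra:
        raise SchemaError(f"{path}: samples not in design: {extra}")
    absent = sorted(set(design_samples) - set(file_samples))
    if absent:
        raise SchemaError(f"{path}: design samples missing from file: {absent}")
    values = df[design_samples].to_numpy()
    as_int = np.asarray(values)
    if not np.issubdtype(as_int.dtype, np.integer):
        rounded = np.rint(values)
        if not np.array_equal(rounded, values) or np.any(~np.isfinite(values)):
            raise FormatError(f"{path}: non-integer count values present")
        as_int = rounded.astype(np.int64)
    if np.any(as_int < 0):
        raise FormatError(f"{path}: negative count values present")
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        counts=as_int.astype(np.int64),
        design=design.loc[design_samples],
    )


def write_counts(cm, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=list(cm.design.index))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    out = design.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Ortholog tables and disease gene lists


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Read a pairwise ortholog TSV with columns gene_a, gene_b."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene_a", "gene_b") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df[["gene_a", "gene_b"]]


def write_ortholog_table(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False)


def read_disease_table(path: str | Path) -> pd.DataFrame:
    """Read a disease differential-gene TSV: gene, direction, log2fc."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str})
    missing = [c for c in ("gene", "direction", "log2fc") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad = ~df["direction"].isin(["up", "down"])
    if bad.any():
        raise FormatError(
            f"{path}: direction must be 'up' or 'down', got "
            f"{df.loc[bad, 'direction'].iloc[0]!r}"
        )
    return df
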