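"""Ortholog map filtering/chaining and hypergeometric gene-set enrichment.

Ortholog maps are inputs (homology inference is out of scope).  The
one-to-one filter removes every pair in which either gene participates in
more than one pair, leaving a bijection; filtered pairwise maps can be
chained through a shared middle species into one-to-one-to-one triples.

Enrichment of an annotated gene set (e.g. TF-bound genes) within a query
list (e.g. disease-down genes) uses the upper-tail hypergeometric
probability P(X >= k) over an explicit background universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffcount import bh_adjust
from .errors import DegenerateDataError


@dataclass
class OrthologMap:
    """Pairwise gene correspondences between two species."""

    pairs: pd.DataFrame  # columns gene_a, gene_b
    species_a: str
    species_b: str
    one_to_one: bool = False

    def __post_init__(self):
        self.pairs = self.pairs[["gene_a", "gene_b"]].reset_index(drop=True)
        if self.one_to_one:
            if self.pairs["gene_a"].duplicated().any() or self.pairs[
                "gene_b"
            ].duplicated().any():
                raise ValueError("map flagged one_to_one but is not a bijection")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))


@dataclass
class ThreeWayMap:
    """Chained one-to-one-to-one triples across three species."""

    triples: pd.DataFrame  # columns gene_a, gene_b, gene_c
    species: tuple[str, str, str]

    def __len__(self) -> int:
        return len(self.triples)

    def a_to_c(self) -> dict[str, str]:
        return dict(zip(self.triples["gene_a"], self.triples["gene_c"]))

    def c_to_a(self) -> dict[str, str]:
        return dict(zip(self.triples["gene_c"], self.triples["gene_a"]))


@dataclass
class DiseaseGeneSet:
    """A disease differential-gene list with per-gene direction and log2FC."""

    disease_label: str
    table: pd.DataFrame  # columns gene, direction, log2fc

    def __post_init__(self):
        t = self.table
        both = t["log2fc"].notna() & t["direction"].notna()
        expected = np.where(t.loc[both, "log2fc"] >= 0, "up", "down")
        if not (t.loc[both, "direction"] == expected).all():
            raise ValueError(
                f"{self.disease_label}: direction labels inconsistent with "
                "log2fc signs"
            )

    def genes(self, direction: str | None = None) -> set[str]:
        t = self.table
        if direction is not None:
            t = t[t["direction"] == direction]
        return set(t["gene"])


@dataclass
class EnrichmentResult:
    k: int  # overlap
    K: int  # annotated genes in universe
    n: int  # query genes in universe
    N: int  # universe size
    p: float
    q: float | None = None

    def as_dict(self) -> dict:
        return {"k": self.k, "K": self.K, "n": self.n, "N": self.N,
                "p": self.p, "q": self.q}


def one_to_one_filter(
    pairs: pd.DataFrame, species_a: str = "a", species_b: str = "b"
) -> OrthologMap:
    """Keep only pairs whose genes each participate in exactly one pair.

    Idempotent; the result is a bijection on the surviving genes.
    """
    pairs = pairs[["gene_a", "gene_b"]].drop_duplicates()
    keep = ~pairs["gene_a"].duplicated(keep=False) & ~pairs["gene_b"].duplicated(
        keep=False
    )
    return OrthologMap(pairs[keep].reset_index(drop=True), species_a, species_b, True)


def chain_orthologs(ab: OrthologMap, bc: OrthologMap) -> ThreeWayMap:
    """Chain two filtered pairwise maps through the shared middle species."""
    if not (ab.one_to_one and bc.one_to_one):
        raise ValueError("both maps must be one_to_one filtered before chaining")
    if ab.species_b != bc.species_a:
        raise ValueError(
            f"cannot chain: middle species {ab.species_b!r} != {bc.species_a!r}"
        )
    merged = ab.pairs.merge(
        bc.pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_c"}),
        on="gene_b",
        how="inner",
    )
    return ThreeWayMap(
        merged[["gene_a", "gene_b", "gene_c"]].reset_index(drop=True),
        (ab.species_a, ab.species_b, bc.species_b),
    )


def hypergeometric_enrichment(
    query: set[str], annotated: set[str], universe: set[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment p = P(X >= k).

    ``annotated`` must be a subset of ``universe``; the query is intersected
    with the universe before testing.  k = |query ∩ annotated|.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not annotated <= universe:
        raise ValueError("annotated set must be a subset of the universe")
    query = query & universe
    k = len(query & annotated)
    K, n, N = len(annotated), len(query), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return EnrichmentResult(k, K, n, N, p)


def enrichment_table(
    queries: dict[str, set[str]],
    annotated_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment over a query x annotated-set grid.

    BH adjustment is applied across all cells of the grid; both raw p and
    q are reported along with -log10(p).
    """
    rows = []
    for qlabel, query in queries.items():
        for alabel, annotated in annotated_sets.items():
            res = hypergeometric_enrichment(query, annotated, universe)
            rows.append(
                {"query": qlabel, "annotated": alabel, **res.as_dict()}
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["minus_log10_p"] = -np.log10(df["p"])
    return df


def association_proportions(
    disease: DiseaseGeneSet,
    associated_genes: set[str],
    gene_map: dict[str, str],
) -> pd.DataFrame:
    """Fraction of mapped disease genes with a binding association.

    ``gene_map`` translates disease-list gene ids into the namespace of
    ``associated_genes`` (a one-to-one ortholog map).  One row per
    direction with counts and the proportion.
    """
    if not set(disease.genes()) & set(gene_map):
        raise DegenerateDataError(
            f"no gene of disease list {disease.disease_label!r} maps through "
            "the ortholog map"
        )
    rows = []
    for direction in ("up", "down"):
        genes = disease.genes(direction)
        mapped = {gene_map[g] for g in genes if g in gene_map}
        n_assoc = len(mapped & associated_genes)
        rows.append(
            {
                "disease": disease.disease_label,
                "direction": direction,
                "n_listed": len(genes),
                "n_mapped": len(mapped),
                "n_associated": n_assoc,
                "proportion": (n_assoc / len(mapped)) if mapped else np.nan,
            }
        )
    return pd.DataFrame(rows)
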