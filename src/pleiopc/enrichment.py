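"""Hypergeometric over-representation analysis of component gene sets.

Component-defining SNPs (those cumulatively carrying a chosen share of a
component's variance) are mapped to genes through a variant-to-gene
table, and the resulting gene set is tested for over-representation in
annotated collections (e.g. non-redundant GO biological processes, or
brain developmental-stage expression sets) against an explicit
background.  Significance is the upper-tail hypergeometric probability
P[X ≥ overlap]; the enrichment ratio is observed / expected overlap;
multiplicity is controlled per collection with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class EnrichmentError(RuntimeError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets with an explicit background universe."""

    sets: dict[str, set[str]]
    background: set[str]

    def restricted(self) -> "GeneSetCollection":
        """Intersect every set with the background."""
        return GeneSetCollection(
            {name: s & self.background for name, s in self.sets.items()},
            set(self.background),
        )


@dataclass
class EnrichmentResult:
    set_name: str
    n_overlap: int
    n_query: int
    n_set: int
    n_background: int
    expected: float
    enrichment_ratio: float
    p_value: float
    fdr: float = float("nan")


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets (name, description, tab-separated genes)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            if name in sets:
                raise EnrichmentError(f"duplicate gene-set name {name!r} in {path}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def read_snp_gene_map(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a SNP→gene table with columns snp_id, gene, v2g_score, within_100kb."""
    df = pd.read_csv(path, sep=delimiter if delimiter else r"\s+",
                     dtype={"snp_id": str, "gene": str})
    required = {"snp_id", "gene", "v2g_score", "within_100kb"}
    if not required.issubset(df.columns):
        raise EnrichmentError(f"SNP→gene map must have columns {sorted(required)}")
    df["within_100kb"] = df["within_100kb"].astype(bool)
    return df


def map_snps_to_genes(
    snps: set[str] | list[str], mapping: pd.DataFrame
) -> tuple[set[str], int]:
    """Genes implicated by a SNP set via a variant-to-gene table.

    For each SNP the top-scoring gene plus every gene flagged as having a
    transcription start site within 100 kb is taken; the union over SNPs
    is returned along with the count of SNPs absent from the table.
    """
    snps = set(snps)
    sub = mapping[mapping["snp_id"].isin(snps)]
    genes: set[str] = set(sub.loc[sub["within_100kb"], "gene"])
    if not sub.empty:
        top = sub.loc[sub.groupby("snp_id")["v2g_score"].idxmax(), "gene"]
        genes |= set(top)
    n_missing = len(snps - set(sub["snp_id"]))
    if n_missing:
        logger.info("%d query SNPs absent from the variant-to-gene table", n_missing)
    return genes, n_missing


def filter_sets(
    coll: GeneSetCollection, min_size: int = 20, max_size: int = 500
) -> GeneSetCollection:
    """Keep sets whose background-restricted size is within [min_size, max_size]."""
    if min_size > max_size:
        raise EnrichmentError("min_size must be <= max_size")
    r = coll.restricted()
    kept = {n: s for n, s in r.sets.items() if min_size <= len(s) <= max_size}
    return GeneSetCollection(kept, r.background)


def hypergeom_ora(
    query: set[str], coll: GeneSetCollection
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per gene set.

    The query is restricted to the background (dropped genes are logged).
    For a background of N genes, a set of K and a query of n drawn genes
    with k in the set, p = P[X ≥ k] under Hypergeometric(N, K, n); the
    expected overlap is n·K/N and the enrichment ratio k / expected.
    BH FDR is computed across all sets of the collection.
    """
    coll = coll.restricted()
    stray = query - coll.background
    if stray:
        logger.warning("dropping %d query genes absent from background", len(stray))
    query = set(query) & coll.background
    if not query:
        raise EnrichmentError("query is empty after background restriction")
    n_bg = len(coll.background)
    n_query = len(query)
    results: list[EnrichmentResult] = []
    for name, geneset in coll.sets.items():
        k = len(query & geneset)
        expected = n_query * len(geneset) / n_bg
        p = float(hypergeom.sf(k - 1, n_bg, len(geneset), n_query))
        results.append(
            EnrichmentResult(
                set_name=name,
                n_overlap=k,
                n_query=n_query,
                n_set=len(geneset),
                n_background=n_bg,
                expected=expected,
                enrichment_ratio=k / expected if expected > 0 else float("nan"),
                p_value=min(p, 1.0),
            )
        )
    if results:
        _, fdr, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    return results


def stage_expression_test(
    query: set[str], stage_sets: GeneSetCollection
) -> list[EnrichmentResult]:
    """Developmental-stage expression enrichment.

    The same hypergeometric over-representation computation applied to
    stage-specific differentially-expressed gene sets (one per brain
    developmental stage), with FDR across stages.
    """
    return hypergeom_ora(query, stage_sets)


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Long-format results table sorted by FDR then p."""
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df = df.sort_values(["fdr", "p_value", "set_name"]).reset_index(drop=True)
    return df
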