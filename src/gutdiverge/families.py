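"""Gene-family (protein-domain) level expression and enrichment statistics.

A gene family is the set of genes carrying a given protein domain (PFAM
accession).  Two complementary views:

* cumulative expression share — the family's summed FPKM divided by the
  summed FPKM of *all* genes in the same library.  A descriptive
  abundance measure; a gene carrying several domains contributes fully
  to each of its families, so shares are not a partition and may sum to
  more than 1 across families.
* family enrichment — an exact overlap test between the family's members
  and the tissue-enriched set, within the universe of all genes that
  received an enrichment call.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResultTable
from .io_formats import DomainAnnotation, ExpressionTable
from .stats_core import bh_adjust, overlap_stats_from_counts

logger = logging.getLogger(__name__)

__all__ = [
    "cumulative_family_share",
    "abundant_families",
    "family_enrichment",
    "shared_enriched_families",
]


def cumulative_family_share(
    table: ExpressionTable, domains: DomainAnnotation
) -> pd.DataFrame:
    """Per-family cumulative FPKM share in the tissue and whole libraries.

    Returns a data frame with columns family_id, share_tissue,
    share_whole, n_genes.  The denominator is the total FPKM over all
    genes in the table, annotated or not.
    """
    fpkm_t = table.fpkm_series("tissue")
    fpkm_w = table.fpkm_series("whole")
    total_t = float(fpkm_t.sum())
    total_w = float(fpkm_w.sum())
    if total_t <= 0 or total_w <= 0:
        raise ValueError("total FPKM is zero in at least one library")
    ann = domains.assignments
    ann = ann[ann["gene_id"].isin(fpkm_t.index)]
    merged = ann.assign(
        fpkm_tissue=fpkm_t.loc[ann["gene_id"]].to_numpy(),
        fpkm_whole=fpkm_w.loc[ann["gene_id"]].to_numpy(),
    )
    grouped = merged.groupby("family_id", sort=True).agg(
        share_tissue=("fpkm_tissue", "sum"),
        share_whole=("fpkm_whole", "sum"),
        n_genes=("gene_id", "nunique"),
    )
    grouped["share_tissue"] /= total_t
    grouped["share_whole"] /= total_w
    return grouped.reset_index()


def abundant_families(
    shares: pd.DataFrame, min_share: float = 0.01
) -> pd.DataFrame:
    """Families that dominate the tissue library: share_tissue above the
    cutoff and higher than in the whole-organism library; sorted by
    descending tissue share."""
    keep = (shares["share_tissue"] > min_share) & (
        shares["share_tissue"] > shares["share_whole"]
    )
    out = shares[keep].sort_values(
        "share_tissue", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)


def family_enrichment(
    calls: EnrichmentResultTable,
    domains: DomainAnnotation,
    alpha: float = 0.01,
    correction: str = "none",
    min_family_size: int = 2,
    annotated_only: bool = False,
) -> pd.DataFrame:
    """Exact overlap test of each family against the tissue-enriched set.

    The universe is every gene with an enrichment call (optionally only
    annotated genes).  Families with fewer than ``min_family_size``
    members in the universe are skipped.  Significance defaults to the
    unadjusted p < alpha screen; ``correction='bh'`` switches to
    BH-adjusted q <= alpha.
    """
    universe = calls.gene_ids
    ann = domains.assignments
    ann = ann[ann["gene_id"].isin(universe)]
    if annotated_only:
        universe = set(ann["gene_id"])
        if not universe:
            raise ValueError("no annotated genes in the calls universe")
    enriched = calls.enriched_ids & universe
    N = len(universe)
    n = len(enriched)
    rows = []
    skipped = 0
    for family_id, group in ann.groupby("family_id", sort=True):
        members = set(group["gene_id"])
        if len(members) < min_family_size:
            skipped += 1
            continue
        stats = overlap_stats_from_counts(
            k=len(members & enriched), K=len(members), n=n, N=N
        )
        rows.append(
            {
                "family_id": family_id,
                "k": stats.k,
                "K": stats.K,
                "n": stats.n,
                "N": stats.N,
                "expected": stats.expected,
                "fold": stats.fold,
                "p_value": stats.p_value,
            }
        )
    if skipped:
        logger.info("family_enrichment: skipped %d families with < %d members",
                    skipped, min_family_size)
    df = pd.DataFrame(
        rows,
        columns=["family_id", "k", "K", "n", "N", "expected", "fold", "p_value"],
    )
    if correction == "bh" and len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] <= alpha
    else:
        df["q_value"] = np.nan
        df["significant"] = df["p_value"] < alpha
    return df


def shared_enriched_families(
    res_a: pd.DataFrame, res_b: pd.DataFrame
) -> list[str]:
    """Family ids significantly enriched in both species (sorted)."""
    sig_a = set(res_a.loc[res_a["significant"], "family_id"]) if len(res_a) else set()
    sig_b = set(res_b.loc[res_b["significant"], "family_id"]) if len(res_b) else set()
    return sorted(sig_a & sig_b)
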