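"""Calling tissue-enriched genes from a tissue vs whole-organism library pair.

With one library per condition there is no replicate dispersion to
estimate, so differential expression reduces to the question whether a
gene's share of reads in the tissue library exceeds its share in the
whole-organism library.  That is a one-sided Fisher exact test on the
2x2 table

    (count_tissue, library_size_tissue - count_tissue)
    (count_whole,  library_size_whole  - count_whole)

evaluated on raw counts, with Benjamini–Hochberg correction across all
genes.  FPKM and log2 fold change are computed for display and for the
optional effect-size filter; the test itself never sees FPKM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable
from .stats_core import bh_adjust, hypergeom_upper_tail, log_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResultTable",
    "compute_fpkm",
    "call_tissue_enriched",
    "correlation_qc",
]


def compute_fpkm(count, length_bp, library_size):
    """Fragments per kilobase per million mapped reads.

    FPKM = count * 1e9 / (length_bp * library_size).  Accepts scalars or
    arrays.
    """
    count = np.asarray(count, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_bp <= 0) or np.any(library_size <= 0):
        raise ValueError("length_bp and library_size must be positive")
    out = count * 1e9 / (length_bp * library_size)
    return float(out) if out.ndim == 0 else out


@dataclass
class EnrichmentResultTable:
    """Per-gene tissue-enrichment calls for one species.

    ``calls`` columns: gene_id, fpkm_tissue, fpkm_whole, log2fc, p_value,
    q_value, enriched.
    """

    species_label: str
    calls: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def enriched_ids(self) -> set[str]:
        df = self.calls
        return set(df.loc[df["enriched"], "gene_id"])

    @property
    def gene_ids(self) -> set[str]:
        return set(self.calls["gene_id"])

    def __len__(self) -> int:
        return len(self.calls)

    @classmethod
    def from_enriched_ids(
        cls,
        species_label: str,
        all_gene_ids: Iterable[str],
        enriched_ids: Iterable[str],
    ) -> "EnrichmentResultTable":
        """Construct a minimal result table from a known enriched set.

        Used for truth-level analyses (e.g. conservation parameter
        recovery) where per-gene statistics are not needed.
        """
        all_ids = list(all_gene_ids)
        enriched = set(enriched_ids)
        df = pd.DataFrame(
            {
                "gene_id": all_ids,
                "fpkm_tissue": np.nan,
                "fpkm_whole": np.nan,
                "log2fc": np.nan,
                "p_value": np.nan,
                "q_value": np.nan,
                "enriched": [g in enriched for g in all_ids],
            }
        )
        return cls(species_label=species_label, calls=df, thresholds={"source": "truth"})


def call_tissue_enriched(
    table: ExpressionTable,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    min_log2fc: float = 0.0,
) -> EnrichmentResultTable:
    """Call genes significantly enriched in the tissue library.

    Parameters
    ----------
    table : expression table with raw counts and library sizes.
    alpha : BH-adjusted significance level (q <= alpha).
    pseudocount : FPKM pseudocount for the displayed log2 fold change.
    min_log2fc : minimal log2((fpkm_t+c)/(fpkm_w+c)) required to flag a
        gene, on top of significance and fpkm_tissue > fpkm_whole.
    """
    if table.library_size_tissue <= 0 or table.library_size_whole <= 0:
        raise ValueError("library sizes must be positive")
    lt = int(table.library_size_tissue)
    lw = int(table.library_size_whole)
    N = lt + lw
    ct = table.data["count_tissue"].to_numpy(dtype=np.int64)
    cw = table.data["count_whole"].to_numpy(dtype=np.int64)
    # one-sided exact test per gene: draws = tissue library, successes =
    # this gene's reads pooled over both libraries
    pvals = np.empty(len(ct), dtype=float)
    for i in range(len(ct)):
        pvals[i] = hypergeom_upper_tail(int(ct[i]), int(ct[i] + cw[i]), lt, N)
    qvals = bh_adjust(pvals) if len(pvals) else np.array([])

    fpkm_t = table.fpkm_tissue
    fpkm_w = table.fpkm_whole
    log2fc = np.log2((fpkm_t + pseudocount) / (fpkm_w + pseudocount))
    enriched = (qvals <= alpha) & (fpkm_t > fpkm_w) & (log2fc >= min_log2fc)

    calls = pd.DataFrame(
        {
            "gene_id": table.data["gene_id"].to_numpy(),
            "fpkm_tissue": fpkm_t,
            "fpkm_whole": fpkm_w,
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "enriched": enriched,
        }
    )
    logger.info(
        "%s: %d/%d genes called tissue-enriched (q<=%.3g)",
        table.species_label, int(enriched.sum()), len(calls), alpha,
    )
    return EnrichmentResultTable(
        species_label=table.species_label,
        calls=calls,
        thresholds={
            "alpha": alpha,
            "pseudocount": pseudocount,
            "min_log2fc": min_log2fc,
        },
    )


def correlation_qc(
    table: ExpressionTable, method: str = "pearson", floor: float = 0.6
) -> tuple[float, bool]:
    """Tissue-vs-whole expression correlation across all genes.

    A high correlation indicates the two libraries are comparable under
    whole-transcriptome relative normalisation.  Returns the coefficient
    and a 'comparable' flag (coefficient >= floor).
    """
    r = log_correlation(table.fpkm_tissue, table.fpkm_whole, method=method)
    return r, bool(r >= floor)
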