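"""Single-gene conservation of tissue enrichment across two species.

The comparison universe is the one-to-one ortholog core: gene pairs that
were most likely single-copy in the common ancestor.  Within that core,
conservation is quantified as the overlap between the two species'
tissue-enriched sets, tested with the one-sided hypergeometric
(enrichment direction).  The universe is deliberately the core only —
a whole-genome universe would inflate the fold for genes that cannot
possibly be shared.

Expression-level diagnostics accompany the overlap test: the FPKM
category distribution of a gene set, the depletion of lowly expressed
genes among enriched genes (lower-tail exact test), and the fraction of
a species' enriched genes whose orthologs are barely expressed in the
other species' tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResultTable
from .io_formats import ExpressionTable, OrthologMap
from .stats_core import OverlapStats, overlap_stats_from_counts

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationReport",
    "ExpressionCategoryDistribution",
    "CrossSpeciesExpressionCheck",
    "restrict_to_core",
    "conserved_overlap_test",
    "expression_category_distribution",
    "low_expression_depletion_test",
    "cross_species_expression_check",
    "conserved_gene_report",
]

DEFAULT_FPKM_EDGES = (1.0, 10.0, 100.0)


@dataclass
class ConservationReport:
    """Cross-species overlap of tissue-enriched one-to-one orthologs."""

    n_orthologs: int
    enriched_a_in_core: int
    enriched_b_in_core: int
    shared: int
    stats: OverlapStats
    shared_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        assert self.shared == len(self.shared_pairs)


def restrict_to_core(
    gene_set: Iterable[str], orthomap: OrthologMap, side: str
) -> set[str]:
    """Intersect a gene set with one side of the one-to-one ortholog map."""
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    core = orthomap.ids_a if side == "A" else orthomap.ids_b
    return set(gene_set) & core


def conserved_overlap_test(
    enr_a: EnrichmentResultTable,
    enr_b: EnrichmentResultTable,
    orthomap: OrthologMap,
) -> ConservationReport:
    """Test whether tissue enrichment is shared across the ortholog core.

    N = core size, K/n = per-species enriched genes restricted to the
    core, k = pairs enriched on both sides; one-sided upper-tail p.
    """
    if len(orthomap) == 0:
        raise ValueError("no one-to-one core: ortholog map is empty")
    core_enr_a = restrict_to_core(enr_a.enriched_ids, orthomap, "A")
    core_enr_b = restrict_to_core(enr_b.enriched_ids, orthomap, "B")
    a2b = orthomap.a_to_b
    shared_pairs = sorted(
        (ga, a2b[ga]) for ga in core_enr_a if a2b[ga] in core_enr_b
    )
    stats = overlap_stats_from_counts(
        k=len(shared_pairs),
        K=len(core_enr_a),
        n=len(core_enr_b),
        N=len(orthomap),
    )
    return ConservationReport(
        n_orthologs=len(orthomap),
        enriched_a_in_core=len(core_enr_a),
        enriched_b_in_core=len(core_enr_b),
        shared=len(shared_pairs),
        stats=stats,
        shared_pairs=shared_pairs,
    )


@dataclass
class ExpressionCategoryDistribution:
    """Fractions of a gene set falling in FPKM bins of one library."""

    set_name: str
    bin_edges: tuple[float, ...]
    fractions: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        total = float(np.sum(self.fractions))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    def bin_labels(self) -> list[str]:
        edges = [0.0, *self.bin_edges, np.inf]
        return [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]


def expression_category_distribution(
    gene_set: Iterable[str],
    table: ExpressionTable,
    which: str = "tissue",
    bin_edges: Sequence[float] = DEFAULT_FPKM_EDGES,
    set_name: str = "set",
) -> ExpressionCategoryDistribution:
    """Distribution of a gene set over FPKM categories of one library."""
    fpkm = table.fpkm_series(which)
    members = [g for g in set(gene_set) if g in fpkm.index]
    if not members:
        raise ValueError("gene set has no members with expression records")
    values = fpkm.loc[members].to_numpy(dtype=float)
    edges = np.asarray([0.0, *bin_edges, np.inf], dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    return ExpressionCategoryDistribution(
        set_name=set_name,
        bin_edges=tuple(float(e) for e in bin_edges),
        fractions=counts / counts.sum(),
        n_genes=len(members),
    )


def low_expression_depletion_test(
    gene_set: Iterable[str],
    table: ExpressionTable,
    threshold: float = 1.0,
    which: str = "tissue",
    background_ids: Iterable[str] | None = None,
) -> OverlapStats:
    """Exact test that a gene set is depleted of lowly expressed genes.

    2x2 layout within the background (all genes of the table by default,
    or an explicit background such as the ortholog core): K = set size,
    n = genes below the FPKM threshold, k = set members below threshold;
    the p-value is the lower (depletion) tail.
    """
    fpkm = table.fpkm_series(which)
    background = set(fpkm.index if background_ids is None else background_ids)
    background &= set(fpkm.index)
    if not background:
        raise ValueError("empty background")
    members = set(gene_set) & background
    if not members:
        raise ValueError("gene set has no members within the background")
    low = {g for g in background if fpkm.loc[g] < threshold}
    return overlap_stats_from_counts(
        k=len(members & low),
        K=len(members),
        n=len(low),
        N=len(background),
        alternative="less",
    )


@dataclass
class CrossSpeciesExpressionCheck:
    """Expression of a gene set's orthologs in the other species."""

    fraction_below: float | None
    n_mapped: int
    n_unmappable: int
    threshold: float


def cross_species_expression_check(
    gene_set_a: Iterable[str],
    orthomap: OrthologMap,
    table_b: ExpressionTable,
    threshold: float = 1.0,
    which: str = "tissue",
) -> CrossSpeciesExpressionCheck:
    """Fraction of a species-A gene set whose one-to-one orthologs are
    lowly expressed (FPKM < threshold) in species B's library.

    Genes without a one-to-one ortholog (or whose ortholog lacks an
    expression record) are counted as unmappable, not as low.
    """
    a2b = orthomap.a_to_b
    fpkm_b = table_b.fpkm_series(which)
    genes = set(gene_set_a)
    mapped = [a2b[g] for g in genes if g in a2b and a2b[g] in fpkm_b.index]
    n_unmappable = len(genes) - len(mapped)
    if not mapped:
        return CrossSpeciesExpressionCheck(
            fraction_below=None,
            n_mapped=0,
            n_unmappable=n_unmappable,
            threshold=threshold,
        )
    values = fpkm_b.loc[mapped].to_numpy(dtype=float)
    return CrossSpeciesExpressionCheck(
        fraction_below=float(np.mean(values < threshold)),
        n_mapped=len(mapped),
        n_unmappable=n_unmappable,
        threshold=threshold,
    )


def conserved_gene_report(
    report: ConservationReport,
    symbols: Mapping[str, str] | None = None,
    descriptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per conserved pair: id_A, symbol, id_B, description."""
    symbols = symbols or {}
    descriptions = descriptions or {}
    rows = [
        {
            "gene_id_a": ga,
            "symbol": symbols.get(ga, "NA"),
            "gene_id_b": gb,
            "description": descriptions.get(ga, descriptions.get(gb, "")),
        }
        for ga, gb in report.shared_pairs
    ]
    df = pd.DataFrame(rows, columns=["gene_id_a", "symbol", "gene_id_b", "description"])
    return df.sort_values("gene_id_a", kind="mergesort").reset_index(drop=True)
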