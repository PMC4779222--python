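"""Gene-set level comparisons.

Three tools: the pairwise overlap matrix used to compare independent
studies of the same tissue (row-normalised, hence not symmetric), flat
functional-term over-representation with cross-dataset agreement counts,
and the pathogen-response overlap table that asks whether tissue-enriched
genes coincide with genes differentially expressed upon pathogen
exposure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResultTable
from .io_formats import GeneSetCollection, TermAnnotation
from .stats_core import bh_adjust, overlap_test

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_overlap_matrix",
    "term_enrichment",
    "term_agreement",
    "response_overlap_table",
    "format_ceiling_p",
]


def pairwise_overlap_matrix(sets: GeneSetCollection) -> pd.DataFrame:
    """Percentage of each row set's genes found in each column set.

    value[i, j] = 100 * |set_i ∩ set_j| / |set_i|; the diagonal is 100
    and the matrix is not symmetric unless all sets have equal size.
    """
    names = sets.names()
    if len(names) < 2:
        raise ValueError("need at least two gene sets")
    values = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        sa = sets[a]
        if not sa:
            raise ValueError(f"gene set {a!r} is empty")
        for j, b in enumerate(names):
            values[i, j] = 100.0 * len(sa & sets[b]) / len(sa)
    return pd.DataFrame(values, index=names, columns=names)


def term_enrichment(
    gene_set,
    terms: TermAnnotation,
    universe,
    alpha: float = 0.05,
    correction: str = "bh",
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Flat over-representation test of every annotated term in a gene set.

    Annotations are used as given (no ontology propagation).  Terms with
    fewer than ``min_term_size`` annotated genes in the universe are
    skipped.  Returns one row per tested term with the overlap counts,
    fold, p, q and a significance flag at ``alpha`` after the chosen
    correction ('bh' or 'none').
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    gene_set = set(gene_set) & universe
    ann = terms.assignments
    ann = ann[ann["gene_id"].isin(universe)]
    rows = []
    for term_id, group in ann.groupby("term_id", sort=True):
        members = set(group["gene_id"])
        if len(members) < min_term_size:
            continue
        stats = overlap_test(members, gene_set, universe)
        rows.append(
            {
                "term_id": term_id,
                "k": stats.k,
                "K": stats.K,
                "n": stats.n,
                "N": stats.N,
                "fold": stats.fold,
                "p_value": stats.p_value,
            }
        )
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "fold", "p_value"])
    if correction == "bh" and len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] <= alpha
    else:
        df["q_value"] = np.nan
        df["significant"] = df["p_value"] < alpha
    return df


def term_agreement(per_dataset_enriched_terms: dict[str, set]) -> pd.DataFrame:
    """Count, per term, in how many datasets it was called enriched.

    Takes a mapping dataset name -> set of enriched term ids; returns a
    frame with one row per term appearing in at least one dataset, a
    per-dataset boolean column, and the agreement count, sorted by
    descending count (ties by term id).
    """
    datasets = list(per_dataset_enriched_terms)
    all_terms = sorted(set().union(*per_dataset_enriched_terms.values()))
    rows = []
    for term in all_terms:
        flags = {d: term in per_dataset_enriched_terms[d] for d in datasets}
        rows.append({"term_id": term, **flags, "n_datasets_enriched": sum(flags.values())})
    df = pd.DataFrame(rows, columns=["term_id", *datasets, "n_datasets_enriched"])
    return df.sort_values(
        ["n_datasets_enriched", "term_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def format_ceiling_p(p: float, ns_threshold: float = 0.05) -> str:
    """Human-readable p-value: 'n.s.' at or above the threshold, a plain
    number down to 0.01, and a nearest-power-of-ten ceiling below that
    (e.g. '<10^-12')."""
    if p >= ns_threshold:
        return "n.s."
    if p >= 0.01:
        return f"{p:.2g}"
    if p <= 0.0:
        return "<10^-300"
    exponent = int(math.floor(-math.log10(p)))
    return f"<10^-{exponent}"


def response_overlap_table(
    calls: EnrichmentResultTable,
    response_sets: GeneSetCollection,
    universe=None,
    ns_threshold: float = 0.05,
) -> pd.DataFrame:
    """Overlap of tissue-enriched genes with pathogen-response gene sets.

    One row per response set (named '<pathogen>/<up|down>'): common-gene
    count, enrichment fold, exact upper-tail p, and a display string that
    mirrors print conventions ('n.s.' / power-of-ten ceilings).  Exact
    p-values stay in the machine-readable column.
    """
    universe = set(universe) if universe is not None else calls.gene_ids
    if not universe:
        raise ValueError("universe must be non-empty")
    enriched = calls.enriched_ids
    rows = []
    for name in response_sets.names():
        label = response_sets.species_labels.get(name)
        if label is not None and label != calls.species_label:
            raise ValueError(
                f"response set {name!r} is for species {label!r}, "
                f"calls are for {calls.species_label!r}"
            )
        members = set(response_sets[name])
        if not (members & universe):
            raise ValueError(
                f"response set {name!r} shares no genes with the universe "
                f"(wrong species?)"
            )
        stats = overlap_test(enriched, members, universe)
        rows.append(
            {
                "species": calls.species_label,
                "response": name,
                "common_genes": stats.k,
                "set_size": stats.n,
                "enrichment": stats.fold,
                "p_value": stats.p_value,
                "display_p": format_ceiling_p(stats.p_value, ns_threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "response", "common_genes", "set_size",
            "enrichment", "p_value", "display_p",
        ],
    )
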