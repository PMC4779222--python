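"""End-to-end orchestration: from expression tables and annotations to the
figure/table-shaped reports.

Each stage reads and writes files only — no hidden state — so any stage
can be rerun in isolation and a full run is reproducible bit-for-bit
from the same inputs and configuration.  Every overlap statistic
produced anywhere in the run is collected into ``summary.json``, tagged
with its stage and inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conservation as cons
from . import families as fam
from . import set_comparison as setcmp
from .enrichment import EnrichmentResultTable, call_tissue_enriched, correlation_qc
from .io_formats import (
    read_domain_annotation,
    read_expression_table,
    read_gene_sets,
    read_ortholog_map,
    read_term_annotation,
    write_json_summary,
    write_tsv_report,
)
from .stats_core import OverlapStats

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]

REPORT_FILES = (
    "fig1c_matrix.tsv",
    "fig1d_agreement.tsv",
    "fig2a_conservation.tsv",
    "fig2bc_distributions.tsv",
    "fig3ab_shares.tsv",
    "fig3cd_family_enrichment.tsv",
    "table1_conserved_genes.tsv",
    "table2_response_overlap.tsv",
    "summary.json",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Inputs, output directory and every stage threshold."""

    expr_a: str
    expr_b: str
    orthologs: str
    domains_a: str
    domains_b: str
    terms_a: str
    studies: str
    responses_a: str
    responses_b: str
    out_dir: str
    species_a: str = "species_A"
    species_b: str = "species_B"
    alpha_de: float = 0.05
    alpha_family: float = 0.01
    alpha_term: float = 0.05
    min_share: float = 0.01
    fpkm_low: float = 1.0
    ns_threshold: float = 0.05
    pseudocount: float = 1.0
    min_log2fc: float = 0.0
    family_correction: str = "none"
    term_correction: str = "bh"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_family", "alpha_term", "min_share",
                     "ns_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, out_dir: str | Path,
                   **overrides) -> "PipelineConfig":
        """Config pointing at a directory written by the simulator."""
        b = Path(bundle_dir)
        return cls(
            expr_a=str(b / "expr_a.tsv"),
            expr_b=str(b / "expr_b.tsv"),
            orthologs=str(b / "orthologs.tsv"),
            domains_a=str(b / "domains_a.tsv"),
            domains_b=str(b / "domains_b.tsv"),
            terms_a=str(b / "terms_a.tsv"),
            studies=str(b / "studies.gmt"),
            responses_a=str(b / "responses_a.gmt"),
            responses_b=str(b / "responses_b.gmt"),
            out_dir=str(out_dir),
            **overrides,
        )

    def thresholds(self) -> dict:
        return {
            "alpha_de": self.alpha_de,
            "alpha_family": self.alpha_family,
            "alpha_term": self.alpha_term,
            "min_share": self.min_share,
            "fpkm_low": self.fpkm_low,
            "ns_threshold": self.ns_threshold,
            "pseudocount": self.pseudocount,
            "min_log2fc": self.min_log2fc,
            "family_correction": self.family_correction,
            "term_correction": self.term_correction,
        }


class _Run:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.overlap_stats: list[dict] = []
        self.extras: dict = {}

    def record(self, stage: str, name: str, stats: OverlapStats) -> None:
        self.overlap_stats.append({"stage": stage, "name": name, **stats.to_dict()})


def _stage(run: _Run, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the nine reports; returns the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    run = _Run(config)

    with _stage(run, "enrichment_calling"):
        expr_a = read_expression_table(config.expr_a, config.species_a)
        expr_b = read_expression_table(config.expr_b, config.species_b)
        calls = {}
        for expr in (expr_a, expr_b):
            res = call_tissue_enriched(
                expr, alpha=config.alpha_de,
                pseudocount=config.pseudocount, min_log2fc=config.min_log2fc,
            )
            r, ok = correlation_qc(expr)
            run.extras[f"correlation_qc_{expr.species_label}"] = {
                "r": r, "comparable": ok,
            }
            calls[expr.species_label] = res
            write_tsv_report(res.calls, run.out / f"calls_{expr.species_label}.tsv")
        calls_a = calls[config.species_a]
        calls_b = calls[config.species_b]

    with _stage(run, "cross_study_comparison"):
        studies = read_gene_sets(config.studies, format="gmt",
                                 species_label=config.species_a)
        study_sets = dict(studies.sets)
        study_sets["this_study"] = frozenset(calls_a.enriched_ids)
        from .io_formats import GeneSetCollection

        all_sets = GeneSetCollection(sets=study_sets)
        matrix = setcmp.pairwise_overlap_matrix(all_sets)
        write_tsv_report(
            matrix.reset_index(names="set_name"), run.out / "fig1c_matrix.tsv"
        )
        terms_a = read_term_annotation(config.terms_a)
        universe_a = calls_a.gene_ids
        enriched_terms = {}
        for name in all_sets.names():
            df = setcmp.term_enrichment(
                all_sets[name], terms_a, universe_a,
                alpha=config.alpha_term, correction=config.term_correction,
            )
            enriched_terms[name] = set(df.loc[df["significant"], "term_id"])
        agreement = setcmp.term_agreement(enriched_terms)
        write_tsv_report(agreement, run.out / "fig1d_agreement.tsv",
                         sort_by=None)

    with _stage(run, "conservation"):
        orthomap = read_ortholog_map(config.orthologs)
        report = cons.conserved_overlap_test(calls_a, calls_b, orthomap)
        run.record("conservation", "conserved_overlap", report.stats)
        summary_row = pd.DataFrame(
            [
                {
                    "n_orthologs": report.n_orthologs,
                    "enriched_a_in_core": report.enriched_a_in_core,
                    "enriched_b_in_core": report.enriched_b_in_core,
                    "shared": report.shared,
                    "fold": report.stats.fold,
                    "p_value": report.stats.p_value,
                }
            ]
        )
        write_tsv_report(summary_row, run.out / "fig2a_conservation.tsv")
        write_tsv_report(
            cons.conserved_gene_report(report),
            run.out / "table1_conserved_genes.tsv",
        )

        # expression-category distributions and low-expression depletion
        dist_rows = []
        core_a = orthomap.ids_a & calls_a.gene_ids
        core_b = orthomap.ids_b & calls_b.gene_ids
        b2a, a2b = orthomap.b_to_a, orthomap.a_to_b
        panels = [
            (expr_a, "enriched_A", calls_a.enriched_ids & core_a),
            (expr_a, "orthologs_of_enriched_B", {b2a[g] for g in calls_b.enriched_ids & core_b}),
            (expr_a, "all_core_A", core_a),
            (expr_b, "enriched_B", calls_b.enriched_ids & core_b),
            (expr_b, "orthologs_of_enriched_A", {a2b[g] for g in calls_a.enriched_ids & core_a}),
            (expr_b, "all_core_B", core_b),
        ]
        for expr, name, gene_set in panels:
            if not gene_set:
                logger.warning("distribution panel %s is empty; skipped", name)
                continue
            dist = cons.expression_category_distribution(
                gene_set, expr, which="tissue", set_name=name
            )
            for label, frac in zip(dist.bin_labels(), dist.fractions):
                dist_rows.append(
                    {
                        "species": expr.species_label,
                        "set_name": name,
                        "fpkm_bin": label,
                        "fraction": float(frac),
                        "n_genes": dist.n_genes,
                    }
                )
        write_tsv_report(pd.DataFrame(dist_rows), run.out / "fig2bc_distributions.tsv",
                         sort_by=None)

        for expr, callset, core in (
            (expr_a, calls_a, core_a),
            (expr_b, calls_b, core_b),
        ):
            enr_core = callset.enriched_ids & core
            if enr_core:
                stats = cons.low_expression_depletion_test(
                    enr_core, expr, threshold=config.fpkm_low,
                    background_ids=core,
                )
                run.record("conservation",
                           f"low_expression_depletion_{expr.species_label}", stats)
        chk_ab = cons.cross_species_expression_check(
            calls_a.enriched_ids, orthomap, expr_b, threshold=config.fpkm_low
        )
        chk_ba = cons.cross_species_expression_check(
            calls_b.enriched_ids, orthomap.swapped(), expr_a,
            threshold=config.fpkm_low,
        )
        run.extras["cross_species_low_expression"] = {
            "enriched_A_in_B": dataclasses.asdict(chk_ab),
            "enriched_B_in_A": dataclasses.asdict(chk_ba),
        }

    with _stage(run, "family_analysis"):
        domains_a = read_domain_annotation(config.domains_a)
        domains_b = read_domain_annotation(config.domains_b)
        share_rows = []
        fam_rows = []
        fam_results = {}
        for expr, callset, domains in (
            (expr_a, calls_a, domains_a),
            (expr_b, calls_b, domains_b),
        ):
            shares = fam.cumulative_family_share(expr, domains)
            top = fam.abundant_families(shares, min_share=config.min_share)
            top.insert(0, "species", expr.species_label)
            share_rows.append(top)
            enr = fam.family_enrichment(
                callset, domains, alpha=config.alpha_family,
                correction=config.family_correction,
            )
            fam_results[expr.species_label] = enr
            enr = enr.copy()
            enr.insert(0, "species", expr.species_label)
            fam_rows.append(enr)
        shared = fam.shared_enriched_families(
            fam_results[config.species_a], fam_results[config.species_b]
        )
        run.extras["shared_enriched_families"] = shared
        write_tsv_report(pd.concat(share_rows, ignore_index=True),
                         run.out / "fig3ab_shares.tsv", sort_by=None)
        fam_table = pd.concat(fam_rows, ignore_index=True)
        fam_table["shared"] = fam_table["family_id"].isin(shared)
        write_tsv_report(fam_table, run.out / "fig3cd_family_enrichment.tsv",
                         sort_by=None)

    with _stage(run, "pathogen_response_overlap"):
        rows = []
        for callset, path in (
            (calls_a, config.responses_a),
            (calls_b, config.responses_b),
        ):
            resp = read_gene_sets(path, format="gmt",
                                  species_label=callset.species_label)
            table = setcmp.response_overlap_table(
                callset, resp, ns_threshold=config.ns_threshold
            )
            rows.append(table)
            from .stats_core import overlap_test

            for _, row in table.iterrows():
                run.overlap_stats.append(
                    {
                        "stage": "pathogen_response_overlap",
                        "name": f"{row['species']}:{row['response']}",
                        "k": int(row["common_genes"]),
                        "n": int(row["set_size"]),
                        "fold": float(row["enrichment"]),
                        "p_value": float(row["p_value"]),
                    }
                )
        write_tsv_report(pd.concat(rows, ignore_index=True),
                         run.out / "table2_response_overlap.tsv", sort_by=None)

    with _stage(run, "summary"):
        write_json_summary(
            {
                "thresholds": run.config.thresholds(),
                "overlap_stats": run.overlap_stats,
                "extras": run.extras,
                "seed": run.config.seed,
            },
            run.out / "summary.json",
        )
    return run.out
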