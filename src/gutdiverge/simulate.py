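"""Synthetic two-species tissue/whole-organism RNA-seq datasets.

The generator emulates the statistical structure of a comparative
intestinal-transcriptome experiment between two nematode species:

* two gene catalogs joined by a one-to-one ortholog core, the remainder
  lineage-specific;
* protein-domain families with power-law sizes; flat functional-term
  annotations;
* log-normal baseline expression shared across orthologs (with species
  jitter), Poisson read counts from single tissue and whole-organism
  libraries;
* a planted tissue-enrichment effect, with a tunable probability that a
  core gene enriched in species A is also enriched in species B;
* pathogen-response gene sets whose coupling to the tissue-enriched pool
  differs per species, and noisy replicate "study" gene sets.

Planted tissue-enriched genes are drawn only from genes whose baseline
FPKM is at least ``enrichment_min_baseline_fpkm`` (default 1): observed
tissue-enriched sets are depleted of lowly expressed genes, and a planted
effect on a silent gene would be biologically meaningless.

Everything is deterministic under (config, seed); the ground truth is
recorded so every downstream stage can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .io_formats import (
    DomainAnnotation,
    ExpressionTable,
    GeneSetCollection,
    OrthologMap,
    TermAnnotation,
    write_annotation,
    write_expression_table,
    write_gene_sets_gmt,
    write_ortholog_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "Catalog",
    "SimBundle",
    "simulate_catalog",
    "simulate_expression_and_counts",
    "simulate_response_sets",
    "simulate_study_variants",
    "generate",
    "expected_conserved_overlap",
]

PATHOGENS = ("B_thuringiensis", "S_aureus", "S_marcescens", "X_nematophila")


@dataclass
class SimConfig:
    """Parameters of the two-species generator.

    Defaults reproduce the magnitudes of the study system: ~20k/24k genes,
    a 5985-pair one-to-one core, 724/20000 and 464/24000 enriched
    fractions, paired single libraries of ~4e7 mapped reads, and a
    conservation probability calibrated so that the expected shared-core
    overlap is ~15 genes.  ``size_factor`` scales the catalog and library
    sizes down uniformly for fast runs.
    """

    # catalog
    n_genes_a: int = 20000
    n_genes_b: int = 24000
    n_core: int = 5985
    # enrichment truth
    frac_enriched_a: float = 724 / 20000
    frac_enriched_b: float = 464 / 24000
    conservation_prob: float = 0.105
    enrichment_log2_effect: float = 3.0
    enrichment_min_baseline_fpkm: float = 1.0
    # families and terms
    n_families: int = 1200
    family_size_exponent: float = 1.8
    max_family_size: int = 400
    families_per_gene_max: int = 3
    n_terms: int = 600
    terms_per_gene_max: int = 5
    # expression model
    baseline_log10_fpkm_mean: float = 0.7
    baseline_log10_fpkm_sd: float = 0.8
    ortholog_jitter_sd: float = 0.15
    tissue_noise_sd: float = 0.0
    nb_dispersion: float = 0.0  # 0 = Poisson counts
    library_size: int = 40_000_000
    mean_gene_length: float = 1500.0
    # pathogen-response sets
    coupling_a: float = 0.35
    coupling_b: float = 0.0
    n_response_sets: int = 8  # 4 pathogens x up/down
    response_set_size: int = 100
    # planted family / term signal
    n_shared_enriched_families: int = 5
    n_private_enriched_families_a: int = 8
    n_private_enriched_families_b: int = 6
    family_signal_genes: int = 12
    n_signal_terms: int = 8
    term_signal_genes: int = 15
    # cross-study replicates
    n_studies: int = 5
    study_noise: float = 0.4
    # global
    size_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_enriched_a", "frac_enriched_b", "conservation_prob",
            "coupling_a", "coupling_b", "study_noise",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_core > min(self.n_genes_a, self.n_genes_b):
            raise ValueError("n_core cannot exceed either catalog size")
        if self.size_factor <= 0:
            raise ValueError("size_factor must be positive")

    def scaled(self) -> "SimConfig":
        """Config with catalog and library sizes scaled by ``size_factor``."""
        if self.size_factor == 1.0:
            return self
        f = self.size_factor
        return dataclasses.replace(
            self,
            n_genes_a=max(10, round(self.n_genes_a * f)),
            n_genes_b=max(10, round(self.n_genes_b * f)),
            n_core=max(0, round(self.n_core * f)),
            library_size=max(1000, round(self.library_size * f)),
            n_families=max(5, round(self.n_families * f)),
            n_terms=max(5, round(self.n_terms * f)),
            size_factor=1.0,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Catalog:
    """Gene identifiers and static annotations for both species."""

    ids_a: list[str]
    ids_b: list[str]
    orthologs: OrthologMap
    domains_a: DomainAnnotation
    domains_b: DomainAnnotation
    terms_a: TermAnnotation
    terms_b: TermAnnotation


@dataclass
class SimTruth:
    """Planted ground truth of a synthetic bundle."""

    enriched_a: set[str]
    enriched_b: set[str]
    conserved_pairs: list[tuple[str, str]]
    shared_families: list[str]
    private_families_a: list[str]
    private_families_b: list[str]
    signal_terms: list[str]
    coupling: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "enriched_a": sorted(self.enriched_a),
            "enriched_b": sorted(self.enriched_b),
            "conserved_pairs": [list(p) for p in self.conserved_pairs],
            "shared_families": list(self.shared_families),
            "private_families_a": list(self.private_families_a),
            "private_families_b": list(self.private_families_b),
            "signal_terms": list(self.signal_terms),
            "coupling": dict(self.coupling),
        }


@dataclass
class SimBundle:
    """A complete synthetic two-species dataset plus its ground truth."""

    config: SimConfig
    catalog: Catalog
    expr_a: ExpressionTable
    expr_b: ExpressionTable
    response_a: GeneSetCollection
    response_b: GeneSetCollection
    studies: GeneSetCollection
    truth: SimTruth


# ---------------------------------------------------------------------------
# catalog


def _assign_families(
    gene_ids: list[str], config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n_fam = config.n_families
    ranks = np.arange(1, n_fam + 1, dtype=float)
    weights = ranks ** (-config.family_size_exponent)
    weights /= weights.sum()
    n = len(gene_ids)
    kmax = config.families_per_gene_max
    n_per_gene = rng.integers(1, kmax + 1, size=n)
    draws = rng.choice(n_fam, size=(n, kmax), p=weights)
    genes, fams = [], []
    for i in range(n):
        for f in np.unique(draws[i, : n_per_gene[i]]):
            genes.append(gene_ids[i])
            fams.append(int(f))
    df = pd.DataFrame({"gene_id": genes, "fam_idx": fams})
    # enforce the family-size truncation: oversized families shed random
    # members; genes left family-less are reassigned uniformly
    sizes = df.groupby("fam_idx")["gene_id"].transform("size")
    keep = np.ones(len(df), dtype=bool)
    for fam, grp in df[sizes > config.max_family_size].groupby("fam_idx"):
        drop = rng.choice(
            grp.index.to_numpy(), size=len(grp) - config.max_family_size,
            replace=False,
        )
        keep[df.index.get_indexer(drop)] = False
    df = df[keep]
    lost = sorted(set(gene_ids) - set(df["gene_id"]))
    if lost:
        # reassign only into families with spare capacity
        counts = df["fam_idx"].value_counts().to_dict()
        open_fams = [f for f in range(n_fam)
                     if counts.get(f, 0) < config.max_family_size]
        rows = []
        for g in lost:
            f = int(rng.choice(open_fams))
            rows.append((g, f))
            counts[f] = counts.get(f, 0) + 1
            if counts[f] >= config.max_family_size:
                open_fams.remove(f)
        extra = pd.DataFrame(rows, columns=["gene_id", "fam_idx"])
        df = pd.concat([df, extra], ignore_index=True)
    df["family_id"] = [f"FAM{idx:05d}" for idx in df["fam_idx"]]
    return df[["gene_id", "family_id"]].drop_duplicates().reset_index(drop=True)


def _assign_terms(
    gene_ids: list[str], config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n_terms = config.n_terms
    n = len(gene_ids)
    n_per_gene = rng.integers(0, config.terms_per_gene_max + 1, size=n)
    genes, terms = [], []
    draws = rng.integers(0, n_terms, size=(n, config.terms_per_gene_max))
    for i in range(n):
        for t in np.unique(draws[i, : n_per_gene[i]]):
            genes.append(gene_ids[i])
            terms.append(int(t))
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "term_id": [f"T{t:05d}" for t in terms],
        }
    )
    df["term_label"] = [f"process {t}" for t in df["term_id"]]
    return df.drop_duplicates(subset=["gene_id", "term_id"]).reset_index(drop=True)


def simulate_catalog(
    config: SimConfig, rng: np.random.Generator | None = None
) -> Catalog:
    """Gene catalogs, one-to-one ortholog core, domain and term annotations."""
    cfg = config.scaled()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids_a = [f"gA{i:06d}" for i in range(cfg.n_genes_a)]
    ids_b = [f"gB{i:06d}" for i in range(cfg.n_genes_b)]
    idx_a = rng.choice(cfg.n_genes_a, size=cfg.n_core, replace=False)
    idx_b = rng.choice(cfg.n_genes_b, size=cfg.n_core, replace=False)
    pairs = pd.DataFrame(
        {
            "gene_a": [ids_a[i] for i in idx_a],
            "gene_b": [ids_b[i] for i in idx_b],
        }
    )
    orthologs = OrthologMap(pairs)
    return Catalog(
        ids_a=ids_a,
        ids_b=ids_b,
        orthologs=orthologs,
        domains_a=DomainAnnotation(_assign_families(ids_a, cfg, rng)),
        domains_b=DomainAnnotation(_assign_families(ids_b, cfg, rng)),
        terms_a=TermAnnotation(_assign_terms(ids_a, cfg, rng)),
        terms_b=TermAnnotation(_assign_terms(ids_b, cfg, rng)),
    )


# ---------------------------------------------------------------------------
# expression


def _sample_counts(
    lam: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.nb_dispersion > 0:
        # gamma-Poisson mixture with Var = mu + dispersion * mu^2
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, lam / shape)
    return rng.poisson(lam)


def simulate_expression_and_counts(
    config: SimConfig,
    catalog: Catalog,
    rng: np.random.Generator,
    with_counts: bool = True,
) -> tuple[ExpressionTable, ExpressionTable, SimTruth]:
    """Planted-truth expression tables for both species.

    Baseline log10 FPKM is normal, shared across ortholog pairs up to a
    species jitter.  Enriched genes (chosen among baselines above the
    eligibility floor) have their tissue-library expectation multiplied
    by 2**enrichment_log2_effect; enrichment of the B copy of a core pair
    is conditioned on the A copy via ``conservation_prob``.  Read counts
    are Poisson with expectation FPKM * length * library_size / 1e9, and
    the reported FPKM columns are recomputed from those counts, so the
    tables carry realistic measurement noise.
    """
    cfg = config.scaled()
    na, nb = cfg.n_genes_a, cfg.n_genes_b
    m, s = cfg.baseline_log10_fpkm_mean, cfg.baseline_log10_fpkm_sd

    base_a = rng.normal(m, s, size=na)
    base_b = rng.normal(m, s, size=nb)
    pos_a = {g: i for i, g in enumerate(catalog.ids_a)}
    pos_b = {g: i for i, g in enumerate(catalog.ids_b)}
    pairs = catalog.orthologs.pairs
    core_ia = np.array([pos_a[g] for g in pairs["gene_a"]], dtype=int)
    core_ib = np.array([pos_b[g] for g in pairs["gene_b"]], dtype=int)
    if len(core_ia):
        z = rng.normal(m, s, size=len(core_ia))
        base_a[core_ia] = z + rng.normal(0, cfg.ortholog_jitter_sd, size=len(z))
        base_b[core_ib] = z + rng.normal(0, cfg.ortholog_jitter_sd, size=len(z))

    fpkm_w_a = 10.0 ** base_a
    fpkm_w_b = 10.0 ** base_b
    floor = cfg.enrichment_min_baseline_fpkm

    # species A enriched genes
    n_enr_a = round(cfg.frac_enriched_a * na)
    eligible_a = np.flatnonzero(fpkm_w_a >= floor)
    if len(eligible_a) < n_enr_a:
        logger.warning("only %d eligible genes in A for %d planted effects",
                       len(eligible_a), n_enr_a)
        n_enr_a = len(eligible_a)
    enr_ia = set(rng.choice(eligible_a, size=n_enr_a, replace=False).tolist())

    # species B: conservation coin for core partners of A-enriched genes,
    # remainder of the quota uniform over eligible genes
    n_enr_b = round(cfg.frac_enriched_b * nb)
    eligible_b = np.flatnonzero(fpkm_w_b >= floor)
    conserved_ib: set[int] = set()
    for ia, ib in zip(core_ia, core_ib):
        if ia in enr_ia and fpkm_w_b[ib] >= floor:
            if rng.random() < cfg.conservation_prob:
                conserved_ib.add(int(ib))
    enr_ib = set(conserved_ib)
    remaining = [i for i in eligible_b if i not in enr_ib]
    n_fill = max(0, n_enr_b - len(enr_ib))
    if n_fill > len(remaining):
        n_fill = len(remaining)
    if n_fill:
        enr_ib |= set(rng.choice(remaining, size=n_fill, replace=False).tolist())

    effect = 2.0 ** cfg.enrichment_log2_effect
    fpkm_t_a = fpkm_w_a.copy()
    fpkm_t_b = fpkm_w_b.copy()
    fpkm_t_a[sorted(enr_ia)] *= effect
    fpkm_t_b[sorted(enr_ib)] *= effect
    if cfg.tissue_noise_sd > 0:
        fpkm_t_a *= 10.0 ** rng.normal(0, cfg.tissue_noise_sd, size=na)
        fpkm_t_b *= 10.0 ** rng.normal(0, cfg.tissue_noise_sd, size=nb)

    len_a = np.maximum(200, rng.gamma(4.0, cfg.mean_gene_length / 4.0, size=na)).astype(int)
    len_b = np.maximum(200, rng.gamma(4.0, cfg.mean_gene_length / 4.0, size=nb)).astype(int)
    lib = int(cfg.library_size)

    def _table(ids, lengths, fpkm_t, fpkm_w, label) -> ExpressionTable:
        lam_t = fpkm_t * lengths * lib / 1e9
        lam_w = fpkm_w * lengths * lib / 1e9
        if with_counts:
            ct = _sample_counts(lam_t, cfg, rng)
            cw = _sample_counts(lam_w, cfg, rng)
        else:  # noise-free tables for truth-level analyses
            ct = np.round(lam_t).astype(int)
            cw = np.round(lam_w).astype(int)
        df = pd.DataFrame(
            {
                "gene_id": ids,
                "length_bp": lengths,
                "count_tissue": ct,
                "count_whole": cw,
                "fpkm_tissue": ct * 1e9 / (lengths * lib),
                "fpkm_whole": cw * 1e9 / (lengths * lib),
            }
        )
        return ExpressionTable(
            species_label=label,
            data=df,
            library_size_tissue=lib,
            library_size_whole=lib,
        )

    expr_a = _table(catalog.ids_a, len_a, fpkm_t_a, fpkm_w_a, "species_A")
    expr_b = _table(catalog.ids_b, len_b, fpkm_t_b, fpkm_w_b, "species_B")

    enriched_a = {catalog.ids_a[i] for i in enr_ia}
    enriched_b = {catalog.ids_b[i] for i in enr_ib}
    a2b = catalog.orthologs.a_to_b
    conserved_pairs = sorted(
        (ga, a2b[ga])
        for ga in enriched_a
        if ga in a2b and a2b[ga] in enriched_b
    )
    truth = SimTruth(
        enriched_a=enriched_a,
        enriched_b=enriched_b,
        conserved_pairs=conserved_pairs,
        shared_families=[],
        private_families_a=[],
        private_families_b=[],
        signal_terms=[],
        coupling={"species_A": cfg.coupling_a, "species_B": cfg.coupling_b},
    )
    return expr_a, expr_b, truth


# ---------------------------------------------------------------------------
# gene-set layers


def simulate_response_sets(
    config: SimConfig,
    truth: SimTruth,
    catalog: Catalog,
    rng: np.random.Generator,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Pathogen up/down response sets per species.

    Each member is drawn from the planted tissue-enriched pool with the
    species' coupling probability, otherwise uniformly from the whole
    catalog — so at coupling 0 a response set is a uniform random set
    and its overlap fold with the enriched pool is ~1 in expectation.
    """
    cfg = config.scaled()

    def _one_species(ids, enriched, coupling, label):
        enriched = sorted(enriched)
        all_ids = sorted(ids)
        sets, labels = {}, {}
        names = [
            f"{p}/{d}" for p in PATHOGENS for d in ("down", "up")
        ][: cfg.n_response_sets]
        for name in names:
            size = min(cfg.response_set_size, len(ids))
            n_pool = int(rng.binomial(size, coupling)) if enriched else 0
            n_pool = min(n_pool, len(enriched))
            members: set[str] = set()
            if n_pool:
                members |= set(rng.choice(enriched, size=n_pool, replace=False))
            rest = sorted(set(all_ids) - members)
            n_rest = min(size - len(members), len(rest))
            if n_rest:
                members |= set(rng.choice(rest, size=n_rest, replace=False))
            sets[name] = frozenset(members)
            labels[name] = label
        return GeneSetCollection(sets=sets, species_labels=labels)

    resp_a = _one_species(catalog.ids_a, truth.enriched_a, cfg.coupling_a, "species_A")
    resp_b = _one_species(catalog.ids_b, truth.enriched_b, cfg.coupling_b, "species_B")
    return resp_a, resp_b


def simulate_study_variants(
    config: SimConfig,
    truth: SimTruth,
    catalog: Catalog,
    rng: np.random.Generator,
) -> GeneSetCollection:
    """Noisy replicate study sets of the species-A enriched genes.

    Each study replaces a fraction ``study_noise`` of the planted set's
    members with random other genes, emulating partially concordant
    published gene sets.
    """
    cfg = config.scaled()
    planted = sorted(truth.enriched_a)
    others = sorted(set(catalog.ids_a) - set(planted))
    sets, labels = {}, {}
    for i in range(cfg.n_studies):
        n_swap = round(cfg.study_noise * len(planted))
        keep = rng.choice(planted, size=len(planted) - n_swap, replace=False).tolist()
        swapped = rng.choice(others, size=min(n_swap, len(others)), replace=False).tolist()
        name = f"study_{i + 1}"
        sets[name] = frozenset(keep + swapped)
        labels[name] = "species_A"
    return GeneSetCollection(sets=sets, species_labels=labels)


def _plant_family_signal(
    catalog: Catalog, truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> None:
    """Boost chosen families with tissue-enriched members in one or both
    species, so family-level conservation has a known answer."""
    cfg = config.scaled()
    n_total = (
        cfg.n_shared_enriched_families
        + cfg.n_private_enriched_families_a
        + cfg.n_private_enriched_families_b
    )
    # pick family ids away from the very largest (rank-1) families so the
    # planted signal is not drowned by huge baseline memberships
    candidates = [f"FAM{i:05d}" for i in range(cfg.n_families // 4, cfg.n_families)]
    chosen = rng.choice(candidates, size=min(n_total, len(candidates)), replace=False)
    shared = list(chosen[: cfg.n_shared_enriched_families])
    priv_a = list(
        chosen[cfg.n_shared_enriched_families:
               cfg.n_shared_enriched_families + cfg.n_private_enriched_families_a]
    )
    priv_b = list(chosen[cfg.n_shared_enriched_families + cfg.n_private_enriched_families_a:])

    def _plant(domains: DomainAnnotation, enriched: set[str], fams: list[str]) -> None:
        enriched = sorted(enriched)
        rows = []
        for fam in fams:
            n_sig = min(cfg.family_signal_genes, len(enriched))
            for g in rng.choice(enriched, size=n_sig, replace=False):
                rows.append({"gene_id": g, "family_id": fam})
        if rows:
            domains.assignments = (
                pd.concat([domains.assignments, pd.DataFrame(rows)], ignore_index=True)
                .drop_duplicates()
                .reset_index(drop=True)
            )

    _plant(catalog.domains_a, truth.enriched_a, shared + priv_a)
    _plant(catalog.domains_b, truth.enriched_b, shared + priv_b)
    truth.shared_families = sorted(map(str, shared))
    truth.private_families_a = sorted(map(str, priv_a))
    truth.private_families_b = sorted(map(str, priv_b))


def _plant_term_signal(
    catalog: Catalog, truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> None:
    cfg = config.scaled()
    terms = [f"T{i:05d}" for i in range(cfg.n_terms)]
    chosen = rng.choice(terms, size=min(cfg.n_signal_terms, len(terms)), replace=False)
    enriched = sorted(truth.enriched_a)
    rows = []
    for term in chosen:
        n_sig = min(cfg.term_signal_genes, len(enriched))
        for g in rng.choice(enriched, size=n_sig, replace=False):
            rows.append({"gene_id": g, "term_id": term, "term_label": f"process {term}"})
    if rows:
        catalog.terms_a.assignments = (
            pd.concat([catalog.terms_a.assignments, pd.DataFrame(rows)], ignore_index=True)
            .drop_duplicates(subset=["gene_id", "term_id"])
            .reset_index(drop=True)
        )
    truth.signal_terms = sorted(map(str, chosen))


# ---------------------------------------------------------------------------
# composition


def generate(config: SimConfig, out_dir: str | Path | None = None) -> SimBundle:
    """Generate a complete synthetic bundle (optionally written to disk).

    The on-disk layout is directly consumable by the CLI pipeline:
    expr_a.tsv, expr_b.tsv, orthologs.tsv, domains_{a,b}.tsv,
    terms_{a,b}.tsv, responses_{a,b}.gmt, studies.gmt, truth.json.
    """
    rng = np.random.default_rng(config.seed)
    catalog = simulate_catalog(config, rng)
    expr_a, expr_b, truth = simulate_expression_and_counts(config, catalog, rng)
    _plant_family_signal(catalog, truth, config, rng)
    _plant_term_signal(catalog, truth, config, rng)
    resp_a, resp_b = simulate_response_sets(config, truth, catalog, rng)
    studies = simulate_study_variants(config, truth, catalog, rng)
    bundle = SimBundle(
        config=config,
        catalog=catalog,
        expr_a=expr_a,
        expr_b=expr_b,
        response_a=resp_a,
        response_b=resp_b,
        studies=studies,
        truth=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_table(bundle.expr_a, out / "expr_a.tsv")
    write_expression_table(bundle.expr_b, out / "expr_b.tsv")
    write_ortholog_map(bundle.catalog.orthologs, out / "orthologs.tsv")
    write_annotation(bundle.catalog.domains_a, out / "domains_a.tsv")
    write_annotation(bundle.catalog.domains_b, out / "domains_b.tsv")
    write_annotation(bundle.catalog.terms_a, out / "terms_a.tsv")
    write_annotation(bundle.catalog.terms_b, out / "terms_b.tsv")
    write_gene_sets_gmt(bundle.response_a, out / "responses_a.gmt")
    write_gene_sets_gmt(bundle.response_b, out / "responses_b.gmt")
    write_gene_sets_gmt(bundle.studies, out / "studies.gmt")
    payload = {"config": bundle.config.to_dict(), "truth": bundle.truth.to_dict()}
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# analytic expectations


def expected_conserved_overlap(config: SimConfig) -> dict[str, float]:
    """Analytic expectation of the conserved-overlap counts under the
    generator's law.

    Returns expected K (A-enriched in core), n (B-enriched in core),
    k (shared) and the expected enrichment fold k/(K*n/N).  Eligibility
    of ortholog partners is handled through the bivariate-normal orthant
    probability implied by the shared-baseline model.
    """
    cfg = config.scaled()
    m, s = cfg.baseline_log10_fpkm_mean, cfg.baseline_log10_fpkm_sd
    js = cfg.ortholog_jitter_sd
    t = np.log10(cfg.enrichment_min_baseline_fpkm) if cfg.enrichment_min_baseline_fpkm > 0 else -np.inf
    var = s**2 + js**2
    sd = np.sqrt(var)
    p_elig = float(_scipy_stats.norm.sf(t, loc=m, scale=sd))
    if np.isfinite(t):
        corr = s**2 / var
        mvn = _scipy_stats.multivariate_normal(
            mean=[m, m], cov=[[var, corr * var], [corr * var, var]]
        )
        # P(both above t) via complement of the lower-orthant terms
        p_low_low = float(mvn.cdf([t, t]))
        p_both = 1.0 - 2.0 * float(_scipy_stats.norm.cdf(t, loc=m, scale=sd)) + p_low_low
        p_cond = p_both / p_elig  # P(partner eligible | gene eligible)
    else:
        p_cond = 1.0
    n_enr_a = round(cfg.frac_enriched_a * cfg.n_genes_a)
    n_enr_b = round(cfg.frac_enriched_b * cfg.n_genes_b)
    N = cfg.n_core
    K = n_enr_a * N / cfg.n_genes_a  # enriched are uniform among eligible genes
    conserved = K * cfg.conservation_prob * p_cond
    pool_b = cfg.n_genes_b * p_elig
    n_fill = max(0.0, n_enr_b - conserved)
    # chance hits: fills landing on eligible partners of remaining A-enriched
    targets = (K - conserved) * p_cond
    chance = n_fill * targets / max(1.0, pool_b - conserved)
    k = conserved + chance
    # expected B-enriched genes inside the core
    n_core_b = conserved + n_fill * (N * p_elig - conserved) / max(1.0, pool_b - conserved)
    expected_chance = K * n_core_b / N
    return {
        "K": K,
        "n": n_core_b,
        "k": k,
        "fold": k / expected_chance if expected_chance > 0 else float("nan"),
    }
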