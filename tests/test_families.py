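"""Gene-family expression shares and family enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from gutdiverge.enrichment import EnrichmentResultTable, call_tissue_enriched
from gutdiverge.families import (
    abundant_families,
    cumulative_family_share,
    family_enrichment,
    shared_enriched_families,
)
from gutdiverge.io_formats import DomainAnnotation

from conftest import make_expression_table


def make_domains(pairs):
    return DomainAnnotation(
        pd.DataFrame(pairs, columns=["gene_id", "family_id"], dtype=str)
    )


def table_with_fpkm(fpkms_tissue, fpkms_whole=None, ids=None):
    lib, length = 10**6, 1000
    ids = ids or [f"g{i}" for i in range(len(fpkms_tissue))]
    if fpkms_whole is None:
        fpkms_whole = fpkms_tissue
    ct = [int(f * length * lib / 1e9) for f in fpkms_tissue]
    cw = [int(f * length * lib / 1e9) for f in fpkms_whole]
    return make_expression_table(ids, ct, cw, length_bp=length,
                                 library_size_tissue=lib, library_size_whole=lib)


class TestCumulativeShare:
    def test_arithmetic_toy(self):
        t = table_with_fpkm([10, 5, 5], ids=["g1", "g2", "g3"])
        d = make_domains([("g1", "famA"), ("g2", "famA"), ("g3", "famB")])
        s = cumulative_family_share(t, d).set_index("family_id")
        assert s.loc["famA", "share_tissue"] == pytest.approx(0.75)
        assert s.loc["famB", "share_tissue"] == pytest.approx(0.25)
        assert s.loc["famA", "n_genes"] == 2

    def test_single_family_share_is_one(self):
        t = table_with_fpkm([3, 7], ids=["g1", "g2"])
        d = make_domains([("g1", "famA"), ("g2", "famA")])
        s = cumulative_family_share(t, d)
        assert s["share_tissue"].iloc[0] == pytest.approx(1.0)

    def test_multi_domain_gene_counts_fully_in_each_family(self):
        t = table_with_fpkm([10, 10], ids=["g1", "g2"])
        d = make_domains([("g1", "famA"), ("g1", "famB"), ("g2", "famA")])
        s = cumulative_family_share(t, d).set_index("family_id")
        assert s.loc["famA", "share_tissue"] == pytest.approx(1.0)
        assert s.loc["famB", "share_tissue"] == pytest.approx(0.5)
        assert s["share_tissue"].sum() > 1.0  # shares are not a partition

    def test_partition_shares_sum_to_one(self):
        rng = np.random.default_rng(4)
        n = 50
        fpkm = rng.gamma(2, 5, size=n) + 0.1
        t = table_with_fpkm(fpkm)
        d = make_domains(
            [(f"g{i}", f"fam{i % 7}") for i in range(n)]
        )
        s = cumulative_family_share(t, d)
        assert s["share_tissue"].sum() == pytest.approx(1.0, abs=1e-9)
        assert s["share_whole"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_denominator_includes_unannotated_genes(self):
        t = table_with_fpkm([10, 10], ids=["g1", "g2"])
        d = make_domains([("g1", "famA")])
        s = cumulative_family_share(t, d)
        assert s["share_tissue"].iloc[0] == pytest.approx(0.5)

    def test_zero_total_fpkm_raises(self):
        t = make_expression_table(["g1"], [0], [0])
        with pytest.raises(ValueError):
            cumulative_family_share(t, make_domains([("g1", "famA")]))


class TestAbundantFamilies:
    def base_shares(self):
        return pd.DataFrame(
            {
                "family_id": ["peptidase", "rare", "down"],
                "share_tissue": [0.13, 0.009, 0.05],
                "share_whole": [0.02, 0.001, 0.06],
                "n_genes": [10, 2, 5],
            }
        )

    def test_filtering_rules(self):
        kept = abundant_families(self.base_shares())
        # 13%-of-transcriptome family kept; sub-1% and tissue<whole dropped
        assert list(kept["family_id"]) == ["peptidase"]

    def test_sorted_descending(self):
        df = self.base_shares()
        df.loc[1, ["share_tissue", "share_whole"]] = [0.05, 0.01]
        kept = abundant_families(df)
        assert list(kept["share_tissue"]) == sorted(kept["share_tissue"], reverse=True)


class TestFamilyEnrichment:
    def test_enumeration_oracle(self):
        # family of 10 with 8 enriched among 100 enriched of 1000 genes
        ids = [f"g{i}" for i in range(1000)]
        enriched = set(ids[:100])
        fam_members = ids[:8] + ids[100:102]
        d = make_domains([(g, "famX") for g in fam_members])
        calls = EnrichmentResultTable.from_enriched_ids("sp", ids, enriched)
        res = family_enrichment(calls, d).set_index("family_id")
        p_ref = float(scipy_stats.hypergeom.sf(7, 1000, 10, 100))
        assert res.loc["famX", "p_value"] == pytest.approx(p_ref, rel=1e-9)
        assert bool(res.loc["famX", "significant"])

    def test_family_without_enriched_members(self):
        ids = [f"g{i}" for i in range(100)]
        d = make_domains([(g, "famX") for g in ids[50:60]])
        calls = EnrichmentResultTable.from_enriched_ids("sp", ids, set(ids[:10]))
        res = family_enrichment(calls, d).set_index("family_id")
        assert res.loc["famX", "fold"] == 0.0
        assert not bool(res.loc["famX", "significant"])

    def test_family_spanning_universe_not_significant(self):
        ids = [f"g{i}" for i in range(50)]
        d = make_domains([(g, "famAll") for g in ids])
        calls = EnrichmentResultTable.from_enriched_ids("sp", ids, set(ids[:5]))
        res = family_enrichment(calls, d).set_index("family_id")
        assert res.loc["famAll", "fold"] == pytest.approx(1.0)
        assert res.loc["famAll", "p_value"] == pytest.approx(1.0)

    def test_small_families_skipped(self):
        ids = [f"g{i}" for i in range(20)]
        d = make_domains([("g0", "famSolo"), ("g1", "famDuo"), ("g2", "famDuo")])
        calls = EnrichmentResultTable.from_enriched_ids("sp", ids, {"g0"})
        res = family_enrichment(calls, d)
        assert set(res["family_id"]) == {"famDuo"}

    def test_invariant_to_relabeling(self):
        ids = [f"g{i}" for i in range(200)]
        rng = np.random.default_rng(9)
        pairs = [(g, f"fam{rng.integers(0, 10)}") for g in ids]
        enriched = set(rng.choice(ids, 30, replace=False))
        calls = EnrichmentResultTable.from_enriched_ids("sp", ids, enriched)
        res1 = family_enrichment(calls, make_domains(pairs))
        relabel = {f"fam{i}": f"clan_{chr(65 + i)}" for i in range(10)}
        gene_map = {g: f"x_{g}" for g in ids}
        pairs2 = [(gene_map[g], relabel[f]) for g, f in pairs]
        calls2 = EnrichmentResultTable.from_enriched_ids(
            "sp", [gene_map[g] for g in ids], {gene_map[g] for g in enriched})
        res2 = family_enrichment(calls2, make_domains(pairs2))
        assert sorted(res1["p_value"]) == pytest.approx(sorted(res2["p_value"]))
        assert sorted(res1["fold"]) == pytest.approx(sorted(res2["fold"]))

    def test_false_positive_rate_under_random_calls(self):
        rng = np.random.default_rng(17)
        n_genes, n_fams = 4000, 600
        ids = [f"g{i}" for i in range(n_genes)]
        pairs = [(g, f"fam{rng.integers(0, n_fams)}") for g in ids]
        enriched = set(rng.choice(ids, 200, replace=False))
        calls = EnrichmentResultTable.from_enriched_ids("sp", ids, enriched)
        res = family_enrichment(calls, make_domains(pairs))
        assert len(res) >= 500
        assert res["significant"].mean() <= 0.02


class TestSharedFamilies:
    def _result(self, sig_ids, all_ids):
        return pd.DataFrame(
            {"family_id": all_ids, "significant": [f in sig_ids for f in all_ids]}
        )

    def test_disjoint_and_empty(self):
        a = self._result({"f1"}, ["f1", "f2"])
        b = self._result({"f2"}, ["f1", "f2"])
        assert shared_enriched_families(a, b) == []
        assert shared_enriched_families(a, self._result(set(), ["f1"])) == []

    def test_planted_shared_families_recovered(self, desk_bundle):
        calls_a = call_tissue_enriched(desk_bundle.expr_a)
        calls_b = call_tissue_enriched(desk_bundle.expr_b)
        res_a = family_enrichment(calls_a, desk_bundle.catalog.domains_a)
        res_b = family_enrichment(calls_b, desk_bundle.catalog.domains_b)
        shared = shared_enriched_families(res_a, res_b)
        assert shared == desk_bundle.truth.shared_families
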