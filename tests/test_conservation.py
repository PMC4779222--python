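"""Ortholog-level conservation of tissue enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from gutdiverge.conservation import (
    conserved_gene_report,
    conserved_overlap_test,
    cross_species_expression_check,
    expression_category_distribution,
    low_expression_depletion_test,
    restrict_to_core,
)
from gutdiverge.enrichment import EnrichmentResultTable
from gutdiverge.io_formats import OrthologMap, write_tsv_report

from conftest import make_expression_table


def make_map(n, prefix_a="A", prefix_b="B"):
    return OrthologMap(
        pd.DataFrame(
            {
                "gene_a": [f"{prefix_a}{i}" for i in range(n)],
                "gene_b": [f"{prefix_b}{i}" for i in range(n)],
            }
        )
    )


class TestRestrictToCore:
    def test_disjoint_set_is_empty(self):
        assert restrict_to_core({"X1", "X2"}, make_map(5), "A") == set()

    def test_full_side(self):
        m = make_map(4)
        assert restrict_to_core(m.ids_a, m, "A") == m.ids_a

    def test_hand_counted_intersection(self):
        m = make_map(5)
        assert restrict_to_core({"A0", "A3", "Z9"}, m, "A") == {"A0", "A3"}
        assert restrict_to_core({"B1", "A0"}, m, "B") == {"B1"}


def truth_tables(n_core, k, K, n):
    """Planted core with K enriched in A, n in B, k shared pairs."""
    ids_a = [f"A{i}" for i in range(n_core)]
    ids_b = [f"B{i}" for i in range(n_core)]
    enr_a = set(ids_a[:K])
    enr_b = {f"B{i}" for i in range(k)} | {f"B{i}" for i in range(K, K + n - k)}
    ra = EnrichmentResultTable.from_enriched_ids("spA", ids_a, enr_a)
    rb = EnrichmentResultTable.from_enriched_ids("spB", ids_b, enr_b)
    return ra, rb, make_map(n_core)


class TestConservedOverlap:
    def test_study_scale_counts(self):
        ra, rb, m = truth_tables(5985, k=15, K=124, n=107)
        rep = conserved_overlap_test(ra, rb, m)
        assert rep.shared == 15
        assert rep.stats.p_value <= 1e-8
        assert rep.stats.fold == pytest.approx(6.77, abs=0.01)
        assert len(rep.shared_pairs) == 15

    def test_empty_enrichment_side(self):
        ra, rb, m = truth_tables(100, k=0, K=0, n=10)
        rep = conserved_overlap_test(ra, rb, m)
        assert rep.shared == 0 and rep.stats.p_value == 1.0

    def test_empty_map_raises(self):
        ra, rb, _ = truth_tables(10, k=1, K=2, n=2)
        empty = OrthologMap(pd.DataFrame({"gene_a": [], "gene_b": []}))
        with pytest.raises(ValueError, match="one-to-one core"):
            conserved_overlap_test(ra, rb, empty)

    def test_species_symmetry(self):
        ra, rb, m = truth_tables(200, k=5, K=20, n=30)
        fwd = conserved_overlap_test(ra, rb, m)
        rev = conserved_overlap_test(rb, ra, m.swapped())
        assert fwd.shared == rev.shared
        assert fwd.stats.p_value == rev.stats.p_value
        assert fwd.stats.fold == rev.stats.fold

    def test_independent_enrichment_is_calibrated(self):
        # with no planted conservation the overlap p-values behave like a
        # conservative null: few replicates reach 0.05
        rng = np.random.default_rng(5)
        n_core, K, n = 800, 60, 60
        m = make_map(n_core)
        ids_a, ids_b = sorted(m.ids_a), sorted(m.ids_b)
        hits = 0
        reps = 200
        for _ in range(reps):
            ra = EnrichmentResultTable.from_enriched_ids(
                "spA", ids_a, rng.choice(ids_a, K, replace=False))
            rb = EnrichmentResultTable.from_enriched_ids(
                "spB", ids_b, rng.choice(ids_b, n, replace=False))
            if conserved_overlap_test(ra, rb, m).stats.p_value <= 0.05:
                hits += 1
        assert hits / reps <= 0.07


class TestExpressionCategories:
    def test_all_zero_goes_to_lowest_bin(self):
        t = make_expression_table(["a", "b"], [0, 0], [0, 0])
        d = expression_category_distribution({"a", "b"}, t)
        assert d.fractions[0] == 1.0

    def test_default_bins_quartet(self):
        # FPKM 0.5, 2, 20, 200 -> one gene per default bin
        lib, length = 10**6, 1000
        counts = [int(f * length * lib / 1e9) for f in (0.5, 2, 20, 200)]
        t = make_expression_table(["a", "b", "c", "d"], counts, [1] * 4,
                                  length_bp=length, library_size_tissue=lib)
        d = expression_category_distribution({"a", "b", "c", "d"}, t)
        assert list(d.fractions) == pytest.approx([0.25] * 4)
        assert d.bin_labels()[0] == "[0,1)"

    def test_empty_set_raises(self):
        t = make_expression_table(["a"], [1], [1])
        with pytest.raises(ValueError):
            expression_category_distribution(set(), t)


class TestLowExpressionDepletion:
    def test_enumeration_oracle_toy(self):
        # 8 genes, 4 below threshold; the set holds 3 genes, 0 of them low:
        # lower-tail p = P(X <= 0), X ~ Hypergeom(N=8, K=3, n=4)
        lib, length = 10**6, 1000
        fpkms = [0.1, 0.2, 0.5, 0.9, 5, 10, 20, 40]
        counts = [int(f * length * lib / 1e9) for f in fpkms]
        ids = [f"g{i}" for i in range(8)]
        t = make_expression_table(ids, counts, [1] * 8, length_bp=length,
                                  library_size_tissue=lib)
        res = low_expression_depletion_test({"g5", "g6", "g7"}, t)
        p_ref = float(scipy_stats.hypergeom.cdf(0, 8, 3, 4))
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)
        assert res.alternative == "less"

    def test_above_threshold_set_attains_minimal_p(self):
        lib, length = 10**6, 1000
        fpkms = [0.1] * 5 + [10] * 5
        counts = [int(f * length * lib / 1e9) for f in fpkms]
        ids = [f"g{i}" for i in range(10)]
        t = make_expression_table(ids, counts, [1] * 10, length_bp=length,
                                  library_size_tissue=lib)
        high = {f"g{i}" for i in range(5, 10)}
        res = low_expression_depletion_test(high, t)
        # minimal attainable lower-tail p at k=0
        p_min = float(scipy_stats.hypergeom.pmf(0, 10, 5, 5))
        assert res.p_value == pytest.approx(p_min, rel=1e-9)

    def test_uniform_sets_not_depleted(self):
        rng = np.random.default_rng(21)
        n = 400
        fpkm = 10 ** rng.normal(0, 1, n)
        lib, length = 10**7, 1000
        counts = np.round(fpkm * length * lib / 1e9).astype(int)
        ids = [f"g{i}" for i in range(n)]
        t = make_expression_table(ids, counts, [1] * n, length_bp=length,
                                  library_size_tissue=lib)
        hits = 0
        reps = 100
        for _ in range(reps):
            sub = set(rng.choice(ids, 60, replace=False))
            if low_expression_depletion_test(sub, t).p_value <= 0.05:
                hits += 1
        assert hits / reps <= 0.07


class TestCrossSpeciesCheck:
    def test_no_orthologs_all_unmappable(self):
        t_b = make_expression_table(["B0"], [5], [5])
        res = cross_species_expression_check({"X1", "X2"}, make_map(1), t_b)
        assert res.fraction_below is None and res.n_unmappable == 2

    def test_all_orthologs_silent(self):
        m = make_map(3)
        t_b = make_expression_table(["B0", "B1", "B2"], [0, 0, 0], [5, 5, 5])
        res = cross_species_expression_check({"A0", "A1"}, m, t_b)
        assert res.fraction_below == 1.0 and res.n_mapped == 2

    def test_hand_count(self):
        m = make_map(4)
        lib, length = 10**6, 1000
        fpkms = [0.5, 2.0, 0.2, 30.0]
        counts = [int(f * length * lib / 1e9) for f in fpkms]
        t_b = make_expression_table([f"B{i}" for i in range(4)], counts, [1] * 4,
                                    length_bp=length, library_size_tissue=lib)
        res = cross_species_expression_check({"A0", "A1", "A2", "Z"}, m, t_b)
        assert res.n_mapped == 3 and res.n_unmappable == 1
        assert res.fraction_below == pytest.approx(2 / 3)


class TestConservedGeneReport:
    def test_rows_and_round_trip(self, tmp_path):
        ra, rb, m = truth_tables(100, k=15, K=20, n=25)
        rep = conserved_overlap_test(ra, rb, m)
        table = conserved_gene_report(rep, symbols={"A0": "ptr-4"})
        assert len(table) == 15
        assert table.loc[table["gene_id_a"] == "A0", "symbol"].iloc[0] == "ptr-4"
        assert list(table["gene_id_a"]) == sorted(table["gene_id_a"])
        out = tmp_path / "t1.tsv"
        write_tsv_report(table, out)
        back = pd.read_csv(out, sep="\t")
        assert len(back) == 15

    def test_empty_report_keeps_header(self):
        ra, rb, m = truth_tables(50, k=0, K=0, n=0)
        rep = conserved_overlap_test(ra, rb, m)
        table = conserved_gene_report(rep)
        assert len(table) == 0
        assert list(table.columns) == ["gene_id_a", "symbol", "gene_id_b", "description"]
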