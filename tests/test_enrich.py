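"""Hypergeometric enrichment, odds ratios, tissue and chromosome sets."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maternome.datatypes import GeneSetCollection
from maternome.enrich import (
    chromosome_sets,
    derive_tissue_specific,
    enrich_collection,
    hypergeom_test,
    odds_ratio,
)
from maternome.exceptions import AnalysisError


def brute_force_tail(a, K, n, N):
    """Independent oracle: exact integer enumeration of P(X >= a)."""
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(a, min(K, n) + 1)) / comb(N, n)


class TestHypergeom:
    def test_zero_hits_full_tail(self):
        assert hypergeom_test(0, 5, 5, 10) == 1.0

    def test_all_draws_in_set(self):
        """N=10, K=5, n=5, a=5: p = C(5,5)C(5,0)/C(10,5) = 1/252."""
        assert abs(hypergeom_test(5, 5, 5, 10) - 1 / 252) < 1e-15

    def test_matches_enumeration_small_tables(self):
        for N in range(1, 26):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 3):
                    for a in range(0, min(K, n) + 1):
                        assert abs(hypergeom_test(a, K, n, N)
                                   - brute_force_tail(a, K, n, N)) < 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 40).flatmap(
        lambda N: st.tuples(st.just(N), st.integers(0, N), st.integers(0, N))))
    def test_monotone_in_hits(self, table):
        N, K, n = table
        p = [hypergeom_test(a, K, n, N) for a in range(min(K, n) + 1)]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(p, p[1:]))

    def test_inconsistent_table_rejected(self):
        with pytest.raises(AnalysisError):
            hypergeom_test(6, 5, 5, 10)


class TestOddsRatio:
    def test_worked_example(self):
        """a=5, K=10, n=20, N=100: OR = (5*75)/(15*5) = 5.0."""
        assert odds_ratio(5, 10, 20, 100) == 5.0

    def test_zero_cell_haldane_corrected(self):
        value = odds_ratio(5, 5, 5, 20)  # all DE genes in the set
        assert np.isfinite(value) and value > 1

    def test_or_above_one_iff_excess_over_expectation(self):
        for N, K, n in [(30, 10, 9), (40, 20, 11), (25, 5, 10)]:
            for a in range(0, min(K, n) + 1):
                cells = [a, n - a, K - a, N - K - n + a]
                if 0 in cells:
                    continue  # Haldane correction shifts the crossover
                assert (odds_ratio(a, K, n, N) > 1) == (a * N > n * K)


class TestEnrichCollection:
    def _collection(self):
        return GeneSetCollection("c", {
            "hit_set": ("", [f"G{i}" for i in range(10)]),
            "cold_set": ("", [f"G{i}" for i in range(50, 70)]),
            "tiny": ("", ["G0", "G1"]),
        })

    def test_de_equal_to_set_is_top_hit(self):
        background = [f"G{i}" for i in range(100)]
        de = [f"G{i}" for i in range(10)]
        table = enrich_collection(de, background, self._collection())
        assert table.iloc[0]["set_name"] == "hit_set"
        assert table.iloc[0]["count"] == 10
        assert table["p"].min() == table.iloc[0]["p"]

    def test_min_size_skips_sets(self):
        background = [f"G{i}" for i in range(100)]
        table = enrich_collection(["G0"], background, self._collection(), min_size=5)
        assert "tiny" not in set(table["set_name"])
        table_all = enrich_collection(["G0"], background, self._collection(), min_size=1)
        assert "tiny" in set(table_all["set_name"])

    def test_stray_de_gene_rejected(self):
        with pytest.raises(AnalysisError, match="missing from background"):
            enrich_collection(["X1"], ["G0", "G1"], self._collection())

    def test_null_draws_rarely_significant(self):
        rng = np.random.default_rng(4)
        background = [f"G{i}" for i in range(500)]
        sets = {f"S{k}": ("", list(rng.choice(background, 25, replace=False)))
                for k in range(40)}
        coll = GeneSetCollection("null", sets)
        hits = 0
        for seed in range(10):
            de = list(np.random.default_rng(seed).choice(background, 50, replace=False))
            table = enrich_collection(de, background, coll)
            hits += int(table["significant"].sum())
        assert hits <= 2

    def test_bh_q_at_least_p(self):
        background = [f"G{i}" for i in range(100)]
        table = enrich_collection([f"G{i}" for i in range(5)], background,
                                  self._collection())
        assert (table["q"] >= table["p"] - 1e-15).all()


class TestTissueSpecific:
    def test_thirty_fold_rule(self):
        atlas = pd.DataFrame({
            "A": [100.0, 60.0, 5.0],
            "B": [3.0, 3.0, 5.0],
            "C": [3.0, 3.0, 5.0],
        }, index=["hit", "near", "flat"])
        coll = derive_tissue_specific(atlas, ratio=30)
        assert coll.set_names() == ["A"]
        assert coll.members("A") == ["hit"]  # 100 > 90; 60 < 90; all-equal excluded

    def test_zero_median_positive_value_is_specific(self):
        atlas = pd.DataFrame({"A": [7.0], "B": [0.0], "C": [0.0]}, index=["g"])
        coll = derive_tissue_specific(atlas, ratio=30)
        assert coll.members("A") == ["g"]

    def test_all_zero_row_specific_to_nothing(self):
        atlas = pd.DataFrame({"A": [0.0, 9.0], "B": [0.0, 0.1], "C": [0.0, 0.1]},
                             index=["z", "keep"])
        coll = derive_tissue_specific(atlas, ratio=30)
        assert "z" not in sum((coll.members(t) for t in coll.set_names()), [])


class TestChromosomeSets:
    def test_partition(self):
        annot = pd.DataFrame({"gene_id": ["G1", "G2", "G3", "G4"],
                              "chromosome": ["chr1", "chr14", "chrX", "chr14"]})
        coll = chromosome_sets(annot)
        assert len(coll) == 3
        members = sum((coll.members(t) for t in coll.set_names()), [])
        assert sorted(members) == ["G1", "G2", "G3", "G4"]

    def test_planted_chromosome_enriched(self):
        """DE genes concentrated on one chromosome drive OR > 1 and small q."""
        genes = [f"G{i}" for i in range(200)]
        chroms = ["chr14" if i < 40 else f"chr{1 + i % 10}" for i in range(200)]
        annot = pd.DataFrame({"gene_id": genes, "chromosome": chroms})
        de = [f"G{i}" for i in range(30)]  # 30 of 40 chr14 genes
        table = enrich_collection(de, genes, chromosome_sets(annot))
        top = table.iloc[0]
        assert top["set_name"] == "chr14"
        assert top["odds_ratio"] > 1 and top["q"] < 0.05
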