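"""Hypergeometric tails, collection testing, shared terms, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from crossomics import (
    DetectionProfile,
    GeneSetCollection,
    SimConfig,
    generate_detection,
    generate_universe,
    hypergeom_test,
    kegg_map_number,
    rank_terms,
    shared_terms,
    significance_matrix,
)
from crossomics.enrichment import GeneSet, bonferroni
from crossomics.enrichment import test_collection as enrich_collection


def enumeration_oracle(N, K, n, k):
    """Exhaustively enumerate all C(N, n) draws from a universe whose first
    K elements carry the term; count overlap tails.  Independent of the
    log-gamma implementation."""
    term = set(range(K))
    total = ge = le = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        ov = len(term.intersection(draw))
        if ov >= k:
            ge += 1
        if ov <= k:
            le += 1
    return ge / total, le / total


class TestHypergeomTest:
    @pytest.mark.parametrize(
        "N, K, n, k, p_enrich, p_deplete",
        [
            (10, 5, 4, 4, 5 / 210, 1.0),   # all four draws in the term
            (10, 5, 4, 0, 1.0, 5 / 210),   # symmetric: none in the term
        ],
    )
    def test_worked_examples(self, N, K, n, k, p_enrich, p_deplete):
        res = hypergeom_test(N, K, n, k)
        assert res.p_enrich == pytest.approx(p_enrich, abs=1e-12)
        assert res.p_deplete == pytest.approx(p_deplete, abs=1e-12)

    def test_matches_enumeration_small_grid(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        res = hypergeom_test(N, K, n, k)
                        ge, le = enumeration_oracle(N, K, n, k)
                        assert res.p_enrich == pytest.approx(ge, abs=1e-12)
                        assert res.p_deplete == pytest.approx(le, abs=1e-12)

    @given(st.data())
    def test_identity_and_scipy_crosscheck(self, data):
        """p_enrich + p_deplete = 1 + pmf(k); tails agree with scipy's
        independently implemented distribution."""
        N = data.draw(st.integers(1, 5000))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(K, n)))
        res = hypergeom_test(N, K, n, k)
        assert res.p_enrich + res.p_deplete - res.pmf_at_k == pytest.approx(1.0, abs=1e-9)
        assert res.p_enrich == pytest.approx(scipy_hypergeom.sf(k - 1, N, K, n), rel=1e-9, abs=1e-12)
        assert res.p_deplete == pytest.approx(scipy_hypergeom.cdf(k, N, K, n), rel=1e-9, abs=1e-12)

    def test_monotone_in_k(self):
        N, K, n = 200, 30, 80
        ps = [hypergeom_test(N, K, n, k).p_enrich for k in range(0, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_infeasible_k_reports_bound(self):
        with pytest.raises(ValueError, match=r"\[0, 4\]"):
            hypergeom_test(10, 5, 4, 5)


def collection_of(sets):
    return GeneSetCollection(
        "custom", "synthetic",
        {tid: GeneSet(tid, frozenset(genes)) for tid, genes in sets.items()},
    )


class TestCollection:
    def test_full_detection_degenerates_to_one(self):
        coll = collection_of({"t1": {"a", "b"}, "t2": {"b", "c", "d"}})
        profile = DetectionProfile("all", coll.all_genes, "gene_symbol")
        rec = enrich_collection(profile, coll)
        assert (rec["k"] == rec["K"]).all()
        assert (rec["p_enrich"] == 1.0).all()
        assert (rec["p_deplete"] == 1.0).all()

    def test_bonferroni_multiplication(self):
        assert bonferroni(0.001, 288) == pytest.approx(0.288)
        assert bonferroni(0.01, 288) == 1.0

    def test_family_is_number_of_tested_terms(self):
        coll = collection_of({f"t{i}": {f"g{i}", "shared"} for i in range(4)})
        profile = DetectionProfile("d", frozenset({"g0", "shared"}), "gene_symbol")
        rec = enrich_collection(profile, coll)
        np.testing.assert_allclose(
            rec["p_adj_deplete"], np.minimum(1.0, rec["p_deplete"] * len(rec))
        )

    def test_planted_depleted_term_recovered(self):
        wins = 0
        for seed in range(10):
            cfg = SimConfig(
                seed=seed, term_size_range=(50, 50),
                planted_terms=((0, "depleted", 0.1),),
                n_datasets=1,
            )
            uni = generate_universe(cfg)
            rec = enrich_collection(generate_detection(uni)[0], uni.gene_sets)
            best = rec.loc[rec["p_deplete"].idxmin(), "term_id"]
            wins += best == "T000"
        assert wins >= 9

    def test_empty_profile_rejected(self, default_universe):
        with pytest.raises(ValueError):
            enrich_collection(
                DetectionProfile("empty", frozenset(), "gene_id"),
                default_universe.gene_sets,
            )


class TestSharedTerms:
    def test_set_intersection(self):
        rec = lambda terms: pd.DataFrame({"term_id": terms, "p_deplete": 0.5})
        out, count = shared_terms({"d1": rec(["A", "B", "C"]), "d2": rec(["B", "C", "D"])})
        assert count == 2
        assert set(out["d1"]["term_id"]) == {"B", "C"}

    def test_cross_species_kegg_ids_match(self):
        rec = lambda terms: pd.DataFrame({"term_id": terms, "p_deplete": 0.5})
        out, count = shared_terms({"cho": rec(["cge00561"]), "sp20": rec(["mmu00561"])})
        assert count == 1
        assert out["cho"]["shared_key"].tolist() == ["00561"]

    def test_identical_collections_fully_shared(self):
        rec = pd.DataFrame({"term_id": ["A", "B"], "p_deplete": [0.1, 0.2]})
        _, count = shared_terms({"d1": rec, "d2": rec.copy()})
        assert count == 2

    @pytest.mark.parametrize(
        "term_id, key", [("cge00561", "00561"), ("mmu00561", "00561"), ("GO:0005576", "0005576")]
    )
    def test_kegg_map_number(self, term_id, key):
        assert kegg_map_number(term_id) == key


class TestMatrixAndRanking:
    def records(self, ps):
        return pd.DataFrame(
            {
                "term_id": [f"t{i}" for i in range(len(ps))],
                "name": "x",
                "N": 100, "K": 10, "n": 50, "k": 5,
                "p_enrich": ps, "p_deplete": ps,
                "p_adj_enrich": ps, "p_adj_deplete": ps,
            }
        )

    @pytest.mark.parametrize("p, expected", [(1.0, 0.0), (0.01, 2.0), (1e-30, 16.0)])
    def test_neglog10_with_floor(self, p, expected):
        mat = significance_matrix({"d": self.records([p])}, "deplete", p_floor=1e-16)
        assert mat.iloc[0, 0] == pytest.approx(expected)

    def test_rank_orders_by_p(self):
        ranked = rank_terms(self.records([0.2, 0.01, 0.05]), "deplete")
        assert ranked["p_deplete"].tolist() == [0.01, 0.05, 0.2]

    def test_top_k_larger_than_records(self):
        assert len(rank_terms(self.records([0.2, 0.1]), "enrich", top_k=15)) == 2

    def test_tie_break_deterministic(self):
        rec = self.records([0.05, 0.05, 0.05])
        rec.loc[1, "k"] = 9  # larger |k - nK/N| wins the tie
        first = rank_terms(rec, "deplete")
        again = rank_terms(rec.sample(frac=1, random_state=0), "deplete")
        assert first["term_id"].tolist() == again["term_id"].tolist()
        assert first.loc[0, "term_id"] == "t1"
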