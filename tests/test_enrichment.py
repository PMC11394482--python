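"""Over-representation analysis: hypergeometric oracle, BH properties, dot-plot table."""

import itertools
import math

import numpy as np
import pytest

from cmpnomics import (
    GeneSetCollection,
    GroundTruth,
    bh_adjust,
    comparative_dotplot,
    generate_gene_sets,
    ora,
)


def hypergeom_upper_tail_enumeration(N, K, n, k):
    """P(X >= k) by direct combinatorics: count n-subsets of a size-N universe
    hitting the size-K term at least k times."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return hits / total


class TestHypergeometric:
    def test_worked_example_exact_fraction(self):
        """N=10, K=5, n=4, k=4 -> p = C(5,4)/C(10,4) = 5/210."""
        universe = [f"g{i}" for i in range(10)]
        term = set(universe[:5])
        query = set(universe[:4])
        col = GeneSetCollection(terms={"t": ("t", "GO", term)})
        res = ora(query, universe, col)
        assert res.table.iloc[0].p_hyper == pytest.approx(5 / 210, abs=1e-12)
        assert res.table.iloc[0].gene_ratio == "1"  # 4/4 reduced

    def test_zero_hits_give_certain_p(self):
        universe = [f"g{i}" for i in range(10)]
        col = GeneSetCollection(terms={"t": ("t", "GO", set(universe[5:]))})
        res = ora(set(universe[:3]), universe, col)
        # query members are annotated to no term -> n counts only annotated ids
        assert res.table.iloc[0].p_hyper == 1.0

    def test_matches_enumeration_small_grid(self):
        """Spot-check the scipy path against brute-force enumeration (full grid in acceptance).

        A catch-all term annotates the whole universe so the annotated query
        size n equals the query size.
        """
        for N in (5, 8):
            universe = [f"g{i}" for i in range(N)]
            for K in range(1, N + 1):
                term = set(universe[:K])
                for n in range(1, N + 1):
                    query = set(universe[N - n:])
                    k = len(query & term)
                    col = GeneSetCollection(
                        terms={"t": ("t", "GO", term), "all": ("all", "GO", set(universe))}
                    )
                    res = ora(query, universe, col)
                    row = res.table[res.table.term_id == "t"].iloc[0]
                    expected = hypergeom_upper_tail_enumeration(N, K, n, k)
                    assert row.p_hyper == pytest.approx(expected, abs=1e-12)

    def test_gene_ratio_definition(self):
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:10])
        query = set(universe[7:13])  # 3 hits out of 6 annotated query members
        col = GeneSetCollection(terms={"t": ("t", "KEGG", set(universe))})
        col.terms["hit"] = ("hit", "KEGG", term)
        res = ora(query, universe, col)
        row = res.table[res.table.term_id == "hit"].iloc[0]
        assert row.k == 3 and row["n"] == 6
        assert row.gene_ratio == "1/2"
        assert row.gene_ratio_value == pytest.approx(0.5)

    def test_query_outside_universe_rejected(self):
        col = GeneSetCollection(terms={"t": ("t", "GO", {"a"})})
        with pytest.raises(ValueError, match="subset"):
            ora({"zzz"}, {"a", "b"}, col)

    def test_empty_query_flagged(self):
        col = GeneSetCollection(terms={"t": ("t", "GO", {"a"})})
        res = ora(set(), {"a", "b"}, col)
        assert res.empty_query
        assert len(res.table) == 0


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_pointwise_geq_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 30))
            adj = np.array(bh_adjust(list(p)))
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            # monotone in the sorted order
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)
            # invariant under permutation of the input
            perm = rng.permutation(len(p))
            adj_perm = np.array(bh_adjust(list(p[perm])))
            assert adj_perm == pytest.approx(adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_bonferroni_option(self):
        assert bh_adjust([0.01, 0.4], method="bonferroni") == pytest.approx([0.02, 0.8])


class TestDotPlot:
    def _results(self):
        universe = [f"g{i}" for i in range(30)]
        col = GeneSetCollection(
            terms={
                "shared_term": ("s", "GO", set(universe[:10])),
                "other": ("o", "GO", set(universe[10:20])),
            }
        )
        r1 = ora(set(universe[:5]), universe, col)
        r2 = ora(set(universe[2:8]), universe, col)
        return {"KO": r1, "WT": r2}

    def test_no_filters_no_exclusions(self):
        table = comparative_dotplot(self._results()).rows
        assert not table.excluded.any()

    def test_filter_covering_all_terms_excludes_everything(self):
        table = comparative_dotplot(
            self._results(), {"dosage": {"shared_term", "other"}}
        ).rows
        assert table.excluded.all()
        assert (table.exclusion_reason == "dosage").all()

    def test_shared_term_marked_in_both_conditions(self):
        table = comparative_dotplot(self._results()).rows
        shared_rows = table[table.term_id == "shared_term"]
        assert len(shared_rows) == 2
        assert shared_rows.shared.all()

    def test_empty_conditions_rejected(self):
        with pytest.raises(ValueError):
            comparative_dotplot({})


class TestGeneratedCollections:
    def test_gmt_round_trip(self, tmp_path):
        truth = GroundTruth()
        universe = [f"g{i}" for i in range(50)]
        col = generate_gene_sets(10, (5, 15), universe, 0, truth, seed=3)
        col.to_gmt(tmp_path / "c.gmt")
        back = GeneSetCollection.from_gmt(tmp_path / "c.gmt")
        assert {t: m for t, (_, _, m) in back.terms.items()} == {
            t: m for t, (_, _, m) in col.terms.items()
        }

    def test_saturating_term_equals_universe(self):
        truth = GroundTruth()
        universe = [f"g{i}" for i in range(50)]
        col = generate_gene_sets(1, (50, 50), universe, 0, truth, seed=0)
        (_, _, members), = col.terms.values()
        assert members == set(universe)

    def test_planted_terms_bounded(self):
        with pytest.raises(ValueError):
            generate_gene_sets(3, (2, 5), [f"g{i}" for i in range(20)], 5, GroundTruth())

    def test_deterministic_gmt_bytes(self, tmp_path, small_omics):
        _, _, truth = small_omics
        universe = [f"P{i:05d}" for i in range(300)]
        for name in ("a.gmt", "b.gmt"):
            generate_gene_sets(20, (5, 20), universe, 4, truth, seed=9).to_gmt(tmp_path / name)
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()

    def test_planted_terms_rank_highly(self, small_omics):
        """Planted enriched terms land in the top decile by adjusted p across seeds."""
        _, _, truth = small_omics
        universe = [f"P{i:05d}" for i in range(300)]
        de = sorted((truth.all_treatment_de() | truth.all_genotype_de()) & set(universe))
        planted = {"T0000", "T0001"}
        hits, trials = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            col = generate_gene_sets(40, (10, 30), universe, 2, truth, seed=seed)
            res = ora(set(de), universe, col)
            decile = set(res.table.head(max(4, len(res.table) // 10)).term_id)
            for term in planted:
                trials += 1
                hits += term in decile
        assert hits >= 0.9 * trials
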