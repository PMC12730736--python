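"""ORA, weighted set cover and preranked GSEA."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from modnet.enrich import (
    EnrichmentTerm,
    GeneSetCollection,
    gsea_preranked,
    ora,
    read_gmt,
    weighted_set_cover,
    write_gmt,
)


def term(name, members, fdr):
    return EnrichmentTerm(term=name, database="x", overlap=len(members),
                          set_size=len(members), expected=1.0,
                          enrichment_ratio=1.0, pvalue=fdr, fdr=fdr,
                          members=list(members))


class TestOra:
    def test_query_equals_universe(self):
        universe = {f"g{i}" for i in range(30)}
        coll = GeneSetCollection({"S": [f"g{i}" for i in range(10)]})
        res = ora(universe, coll, universe)
        assert res[0].overlap == 10
        assert res[0].pvalue == pytest.approx(1.0)

    def test_closed_form_perfect_overlap(self):
        # all 5 query genes inside a 5-gene set in a 20-gene universe
        universe = {f"g{i}" for i in range(20)}
        coll = GeneSetCollection({"S": [f"g{i}" for i in range(5)]})
        res = ora({f"g{i}" for i in range(5)}, coll, universe)
        assert res[0].pvalue == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_matches_enumeration_oracle(self, rng):
        """Exhaustive hypergeometric tail on small universes."""
        for _ in range(100):
            N = int(rng.integers(8, 30))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            gene_set = list(rng.choice(universe, size=K, replace=False))
            query = set(rng.choice(universe, size=n, replace=False))
            res = ora(query, GeneSetCollection({"S": gene_set}),
                      set(universe))
            k = res[0].overlap
            # P(X >= k) by enumeration over the tail
            total = math.comb(N, n)
            p = sum(math.comb(K, j) * math.comb(N - K, n - j)
                    for j in range(k, min(K, n) + 1)) / total
            assert res[0].pvalue == pytest.approx(p, rel=1e-9)
            assert res[0].expected == pytest.approx(n * K / N)

    def test_label_permutation_invariance(self, rng):
        universe = [f"g{i}" for i in range(40)]
        gene_set = universe[:12]
        query = set(universe[5:20])
        res = ora(query, GeneSetCollection({"S": gene_set}), set(universe))
        relabel = {g: f"x{i}" for i, g in enumerate(universe)}
        res2 = ora({relabel[g] for g in query},
                   GeneSetCollection({"S": [relabel[g] for g in gene_set]}),
                   {relabel[g] for g in universe})
        assert res[0].pvalue == pytest.approx(res2[0].pvalue)

    def test_stray_query_genes_warn_and_empty_universe_fails(self):
        universe = {"a", "b", "c"}
        coll = GeneSetCollection({"S": ["a"]})
        with pytest.warns(UserWarning):
            ora({"a", "zzz"}, coll, universe)
        with pytest.raises(ValueError):
            ora({"a"}, coll, set())

    def test_bh_matches_reference_step_up(self, rng):
        """BH adjustment agrees with a hand-written step-up rule."""
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            got = multipletests(p, method="fdr_bh")[1]
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            assert np.allclose(got, adj)
            assert np.all(got >= p - 1e-12) and np.all(got <= 1.0)


class TestSetCover:
    def test_disjoint_terms_all_selected(self):
        terms = [term("A", {"1", "2"}, 0.01), term("B", {"3"}, 0.02),
                 term("C", {"4", "5", "6"}, 0.03)]
        chosen = weighted_set_cover(terms)
        assert {t.term for t in chosen} == {"A", "B", "C"}
        assert chosen[0].term == "C"  # most coverage first

    def test_subset_term_redundant(self):
        a = term("A", {"1", "2", "3"}, 0.01)
        b = term("B", {"1", "2"}, 0.01)
        chosen = weighted_set_cover([a, b])
        assert [t.term for t in chosen] == ["A"]

    def test_complete_coverage_when_unbounded(self, rng):
        for _ in range(30):
            universe = [f"g{i}" for i in range(20)]
            terms = [
                term(f"T{j}",
                     set(rng.choice(universe,
                                    size=int(rng.integers(1, 8)),
                                    replace=False)),
                     float(rng.uniform(1e-6, 0.05)))
                for j in range(int(rng.integers(2, 9)))
            ]
            chosen = weighted_set_cover(terms)
            covered = set().union(*(t.members for t in chosen))
            assert covered == set().union(*(t.members for t in terms))

    def test_greedy_within_harmonic_bound_of_optimum(self, rng):
        """Classic guarantee: greedy cost <= H(n) x optimal cover cost,
        verified by exhaustive search on <= 8 terms."""
        for _ in range(25):
            universe = [f"g{i}" for i in range(10)]
            terms = [
                term(f"T{j}",
                     set(rng.choice(universe,
                                    size=int(rng.integers(1, 6)),
                                    replace=False)),
                     float(rng.uniform(1e-6, 0.05)))
                for j in range(int(rng.integers(2, 8)))
            ]
            def weight(t):
                return 1.0 / (-math.log10(t.fdr) + 1e-300)

            full = set().union(*(t.members for t in terms))
            chosen = weighted_set_cover(terms)
            greedy_cost = sum(weight(t) for t in chosen)
            best = None
            for r in range(1, len(terms) + 1):
                for combo in itertools.combinations(terms, r):
                    if set().union(*(t.members for t in combo)) == full:
                        cost = sum(weight(t) for t in combo)
                        best = cost if best is None else min(best, cost)
            h = sum(1.0 / k for k in range(1, len(full) + 1))
            assert greedy_cost <= h * best + 1e-12


class TestGsea:
    def test_top_block_es_approaches_one(self):
        genes = [f"g{i}" for i in range(200)]
        ranking = {g: 200 - i for i, g in enumerate(genes)}
        coll = GeneSetCollection({"TOP": genes[:20]})
        res = gsea_preranked(ranking, coll, n_perm=200, seed=1)
        assert res[0].es > 0.9
        assert abs(res[0].es) <= 1.0

    def test_unweighted_matches_classical_ks_oracle(self, rng):
        genes = [f"g{i}" for i in range(100)]
        scores = rng.normal(size=100)
        ranking = dict(zip(genes, scores))
        members = list(rng.choice(genes, size=15, replace=False))
        res = gsea_preranked(ranking, GeneSetCollection({"S": members}),
                             n_perm=200, weight_p=0.0, seed=2)
        # direct unweighted running sum
        order = sorted(genes, key=lambda g: (-ranking[g], g))
        hit = np.array([g in set(members) for g in order])
        up, down = 1.0 / 15, 1.0 / 85
        run = np.cumsum(np.where(hit, up, -down))
        expected = run[int(np.argmax(np.abs(run)))]
        assert res[0].es == pytest.approx(expected, rel=1e-9)

    def test_null_pvalues_uniform(self):
        """Random sets on a random ranking give calibrated p-values."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(600)]
        ranking = dict(zip(genes, rng.normal(size=600)))
        sets = {f"S{i}": list(rng.choice(genes, size=30, replace=False))
                for i in range(200)}
        res = gsea_preranked(ranking, GeneSetCollection(sets),
                             n_perm=1000, seed=11)
        ps = np.array([r.pvalue for r in res])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_sets_skipped_and_nes_sign(self, rng):
        genes = [f"g{i}" for i in range(50)]
        ranking = dict(zip(genes, rng.normal(size=50)))
        coll = GeneSetCollection({"TINY": genes[:2], "OK": genes[:10]})
        with pytest.warns(UserWarning):
            res = gsea_preranked(ranking, coll, n_perm=100, seed=3)
        assert [r.term for r in res] == ["OK"]
        assert np.sign(res[0].nes) == np.sign(res[0].es)


class TestGmtIo:
    def test_roundtrip(self, tmp_path):
        coll = GeneSetCollection({"A": ["x", "y"], "B": ["z"]}, database="db")
        p = tmp_path / "c.gmt"
        write_gmt(coll, str(p))
        back = read_gmt(str(p), database="db")
        assert back.sets == coll.sets

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSetCollection({"E": []})
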