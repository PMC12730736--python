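"""The synthetic study generator: planted structure and determinism."""

import numpy as np
import pandas as pd
import pytest

from modnet import synthio
from modnet.netbuild import read_mitab
from modnet.synthio import (
    simulate_counts,
    simulate_fi_database,
    simulate_interactome,
    simulate_phenotype_panel,
    simulate_variant_tables,
)


class TestVariantTables:
    def test_shared_key_count_and_planted_structure(self):
        t1, t2, truth = simulate_variant_tables(
            n_genes=100, n_shared=50, n_unique_per_subject=10, n_planted=2,
            seed=1)
        k1 = set(map(tuple, t1[["chrom", "pos", "ref", "alt"]].to_numpy()))
        k2 = set(map(tuple, t2[["chrom", "pos", "ref", "alt"]].to_numpy()))
        assert len(k1 & k2) == 50
        planted = t1[t1["gene_symbol"].isin(truth.modifier_genes)]
        planted = planted[~planted[["chrom", "pos"]].apply(tuple, axis=1)
                          .isin(t2[["chrom", "pos"]].apply(tuple, axis=1))]
        assert len(planted) >= 2
        assert (planted["cadd_phred"] >= 30).all()
        af = planted["allele_frequency"]
        assert (af.isna() | (af < 0.01)).all()
        assert (planted["zygosity"] == "hom").all()

    def test_seed_determinism(self):
        a = simulate_variant_tables(n_genes=100, n_shared=50,
                                    n_unique_per_subject=10, n_planted=2,
                                    seed=1)
        b = simulate_variant_tables(n_genes=100, n_shared=50,
                                    n_unique_per_subject=10, n_planted=2,
                                    seed=1)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_unplanted_background_matches_brute_force(self):
        """With nothing planted, the rare+high-impact survivors among
        subject-unique records equal a brute-force row scan."""
        from modnet.variants import SubjectVariantSet, high_impact_filter, \
            rare_filter

        t1, t2, _ = simulate_variant_tables(
            n_genes=200, n_shared=100, n_unique_per_subject=40, n_planted=0,
            seed=3)
        keys2 = set(t2[["chrom", "pos"]].apply(tuple, axis=1))
        uniq = t1[~t1[["chrom", "pos"]].apply(tuple, axis=1).isin(keys2)]
        s = SubjectVariantSet("s1", uniq)
        got = len(high_impact_filter(rare_filter(s), 30))
        expected = sum(
            1 for r in uniq.itertuples()
            if (pd.isna(r.allele_frequency) or r.allele_frequency < 0.01)
            and r.cadd_phred >= 30
        )
        assert got == expected

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0},
        {"n_planted": 20, "n_unique_per_subject": 10},
        {"n_shared": 10**9},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        base = dict(n_genes=50, n_shared=20, n_unique_per_subject=10,
                    n_planted=2, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            simulate_variant_tables(**base)


class TestInteractome:
    def test_two_nodes_one_edge(self):
        edges = simulate_interactome(n_nodes=2, seed=0)
        assert len(edges) == 1

    def test_no_self_loops_or_duplicate_pairs(self):
        edges = simulate_interactome(n_nodes=500, seed=7)
        pairs = [frozenset((e.source, e.target)) for e in edges]
        assert all(len(p) == 2 for p in pairs)
        assert len(pairs) == len(set(pairs))
        assert all(e.taxon == 9606 for e in edges)

    def test_giant_fraction_matches_bfs_oracle(self):
        edges = simulate_interactome(n_nodes=500, seed=7)
        adj: dict[str, set] = {}
        for e in edges:
            adj.setdefault(e.source, set()).add(e.target)
            adj.setdefault(e.target, set()).add(e.source)
        # BFS from an arbitrary node
        seen, frontier = set(), [next(iter(adj))]
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(adj[node] - seen)
        frac = len(seen) / 500
        assert frac >= 0.8  # connected by construction
        import networkx as nx
        g = nx.Graph((e.source, e.target) for e in edges)
        assert len(max(nx.connected_components(g), key=len)) == len(seen)

    def test_degree_parameter_validated(self):
        with pytest.raises(ValueError):
            simulate_interactome(n_nodes=10, degree_model=0)


class TestFiDatabase:
    def test_module_enrichment_and_determinism(self):
        genes = [f"g{i}" for i in range(150)]
        module = genes[:30]
        a = simulate_fi_database(n_nodes=150, module_genes=module,
                                 p_module=0.3, seed=5, genes=genes)
        b = simulate_fi_database(n_nodes=150, module_genes=module,
                                 p_module=0.3, seed=5, genes=genes)
        assert [(e.source, e.target) for e in a] == \
            [(e.source, e.target) for e in b]
        mod = set(module)
        intra = sum(1 for e in a if e.source in mod and e.target in mod)
        n_mod_pairs = 30 * 29 / 2
        outside = [g for g in genes if g not in mod]
        inter = sum(1 for e in a
                    if (e.source in mod) != (e.target in mod))
        # the module must be visibly denser than the background
        assert intra / n_mod_pairs > 0.15


class TestCounts:
    def test_null_log_ratio_centred(self):
        # compare on the CPM scale: raw group means also reflect the
        # (random) library sizes, which is not part of the null effect
        cm, truth = simulate_counts(n_genes=5000, de_fraction=0.0, seed=2)
        labels, (g1, g2) = cm.group_arrays()
        m1 = cm.cpm[g1].mean(axis=1) + 0.5
        m2 = cm.cpm[g2].mean(axis=1) + 0.5
        assert abs(float(np.log2(m1 / m2).mean())) < 0.05
        assert truth.de_genes == []

    def test_deterministic_low_dispersion_limit(self):
        cm, truth = simulate_counts(
            n_genes=50, de_fraction=1.0, effect_log2fc=2.0, dispersion=1e-9,
            libsize_model=synthio.LibsizeModel(mean=5e7, sigma=1e-9), seed=4)
        labels, (g1, g2) = cm.group_arrays()
        de = {g: lfc for g, lfc in truth.de_genes}
        for gene in cm.genes:
            r = cm.counts.loc[gene, g1].mean() / cm.counts.loc[gene, g2].mean()
            expected = 2.0 ** de[gene]
            assert r == pytest.approx(expected, rel=0.15)

    def test_seed_determinism(self):
        a, _ = simulate_counts(n_genes=100, seed=9)
        b, _ = simulate_counts(n_genes=100, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    @pytest.mark.parametrize("kwargs", [
        {"n_reps": 1},
        {"dispersion": -0.1},
        {"de_fraction": 1.5},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_counts(n_genes=20, **kwargs)


class TestPhenotypePanel:
    def test_include_genes_always_annotated(self):
        genes = [f"g{i}" for i in range(60)]
        df = simulate_phenotype_panel(genes, n_terms=4, include=genes[:5],
                                      seed=1)
        assert set(genes[:5]) <= set(df["gene_symbol"])

    def test_single_term_panel(self):
        genes = [f"g{i}" for i in range(30)]
        df = simulate_phenotype_panel(genes, n_terms=1,
                                      genes_per_term=(10, 10), seed=2)
        assert df["hpo_id"].nunique() == 1
        assert df["gene_symbol"].nunique() == len(df)

    def test_determinism_and_reader_roundtrip(self, tmp_path):
        from modnet.integrate import read_hpo_annotations, \
            write_hpo_annotations

        genes = [f"g{i}" for i in range(40)]
        a = simulate_phenotype_panel(genes, seed=3)
        b = simulate_phenotype_panel(genes, seed=3)
        pd.testing.assert_frame_equal(a, b)
        p = tmp_path / "hpo.tsv"
        write_hpo_annotations(a, str(p))
        back = read_hpo_annotations(str(p))
        pd.testing.assert_frame_equal(a, back)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotype_panel([], n_terms=1)


class TestStudyBundle:
    def test_truth_invariants(self, small_bundle):
        truth = small_bundle.truth
        de_names = {g for g, _ in truth.de_genes}
        assert set(truth.modifier_genes) <= de_names
        assert set(truth.modifier_genes) <= set(truth.panel_genes)

    def test_files_roundtrip_through_readers(self, bundle_dir, small_bundle):
        edges = read_mitab(bundle_dir["interactome"])
        assert len(edges) == len(small_bundle.interactome)
        from modnet.rnaseq import CountMatrix
        cm = CountMatrix.from_tsv(bundle_dir["counts"],
                                  small_bundle.counts.groups)
        pd.testing.assert_frame_equal(cm.counts, small_bundle.counts.counts)
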