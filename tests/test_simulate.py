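import numpy as np
import pytest
from scipy import stats

from denet.de_sets import temporal_shift_fraction
from denet.enrichment import enrich
from denet.expression import CountMatrix, call_de, default_contrasts, log2_fold_changes
from denet.pathways import merge_pathways
from denet.simulate import (
    DESpec,
    gen_counts,
    gen_design,
    gen_pathway_cover,
    gen_scale_free,
    gen_terms,
    plant_de_set,
    write_dataset,
)


class TestScaleFree:
    def test_edge_count_contract(self):
        net = gen_scale_free(100, 2, seed=0)
        assert net.n_edges == 2 * (100 - 2)
        assert net.n_nodes == 100

    def test_seed_determinism(self):
        e1 = set(map(frozenset, gen_scale_free(200, 3, seed=5).graph.edges))
        e2 = set(map(frozenset, gen_scale_free(200, 3, seed=5).graph.edges))
        assert e1 == e2

    def test_heavy_tail(self):
        import pandas as pd

        net = gen_scale_free(1000, 3, seed=1)
        deg = pd.Series([d for _, d in net.graph.degree()])
        assert deg.max() > 3 * deg.median()

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_scale_free(3, 3, seed=0)


class TestPathwayCover:
    def test_single_pathway_is_whole_graph(self):
        net = gen_scale_free(60, 2, seed=2)
        coll = gen_pathway_cover(net, n_pathways=1, size_mean=net.n_edges, seed=0)
        assert len(coll) == 1
        assert coll[0].edges == frozenset(map(frozenset, net.graph.edges))

    def test_merge_of_cover_reproduces_graph(self):
        net = gen_scale_free(150, 3, seed=3)
        coll = gen_pathway_cover(net, n_pathways=12, seed=4)
        merged = merge_pathways(coll)
        assert set(map(frozenset, merged.graph.edges)) == set(map(frozenset, net.graph.edges))

    def test_every_edge_has_provenance(self):
        net = gen_scale_free(80, 2, seed=6)
        merged = merge_pathways(gen_pathway_cover(net, n_pathways=6, seed=7))
        assert all(data["pathways"] for _, _, data in merged.graph.edges(data=True))

    def test_pathways_are_connected_edge_subsets(self):
        net = gen_scale_free(100, 2, seed=8)
        for pw in gen_pathway_cover(net, n_pathways=10, seed=9):
            import networkx as nx

            g = pw.to_networkx()
            g.remove_nodes_from(list(nx.isolates(g)))
            assert g.number_of_nodes() == 0 or nx.is_connected(g)


class TestPlantDeSet:
    def test_exact_size(self):
        net = gen_scale_free(100, 2, seed=0)
        assert len(plant_de_set(net, 17, beta=-0.5, seed=1)) == 17

    def test_uniform_beta_matches_network_mean_degree(self):
        net = gen_scale_free(500, 3, seed=0)
        deg = dict(net.graph.degree())
        overall = np.mean(list(deg.values()))
        means = []
        for rep in range(100):
            s = plant_de_set(net, 50, beta=0.0, seed=rep)
            means.append(np.mean([deg[n] for n in s]))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - overall) < 2 * se + 0.05

    def test_extreme_negative_beta_on_star_avoids_center(self):
        import networkx as nx

        from conftest import make_network

        star = make_network(nx.star_graph(10))
        center_picked = sum(
            0 in plant_de_set(star, 3, beta=-5.0, seed=rep) for rep in range(100)
        )
        assert center_picked <= 1

    def test_selection_frequency_tracks_degree_weight(self):
        net = gen_scale_free(300, 3, seed=2)
        nodes = sorted(net.graph.nodes)
        deg = np.array([net.graph.degree[n] for n in nodes])
        freq = np.zeros(len(nodes))
        for rep in range(200):
            s = plant_de_set(net, 30, beta=-0.75, seed=1000 + rep)
            freq += [n in s for n in nodes]
        rho = stats.spearmanr(freq, deg.astype(float) ** -0.75).statistic
        assert rho > 0.5

    def test_infeasible_size_rejected(self):
        net = gen_scale_free(10, 2, seed=0)
        with pytest.raises(ValueError):
            plant_de_set(net, 10, seed=0)


class TestDesign:
    def test_default_sixteen_samples(self):
        design = gen_design()
        assert len(design.sample_ids) == 16
        pairs = list(zip(design.table["timepoint"], design.table["dose_nM"]))
        assert len(pairs) == len(set(pairs))

    def test_custom_two_timepoint_design(self):
        design = gen_design(timepoints=("D0", "D4", "D9"))
        assert len(design.sample_ids) == 1 + 2 * 3


class TestGenCounts:
    def test_seed_determinism(self, tiny_design):
        c1, _ = gen_counts(tiny_design, n_genes=300, seed=11)
        c2, _ = gen_counts(tiny_design, n_genes=300, seed=11)
        np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_truth_genes_exist_and_shifted_subset(self, tiny_design):
        cm, truth = gen_counts(tiny_design, n_genes=500,
                               de_spec=DESpec(frac_de=0.1, shift_frac=0.1), seed=3)
        all_de = truth.all_de_genes()
        assert all_de <= set(cm.gene_ids)
        assert truth.shifted_genes <= all_de
        assert truth.shifted_genes <= truth.high_dose_nonfinal_genes

    def test_poisson_regime_concentrates_observed_lfc(self):
        """dispersion 0, large means: observed lfc within 0.15 of planted 2 for >=95%."""
        design = gen_design(timepoints=("D0", "D4", "D9"))
        cm, truth = gen_counts(
            design, n_genes=2000, de_spec=DESpec(frac_de=0.1, lfc_abs=2.0, shift_frac=0.0),
            dispersion=0.0, mean_log_median=5000.0, mean_log_sigma=0.3, min_mean=1000.0,
            size_factor_range=(1.0, 1.0), seed=21,
        )
        lfc = log2_fold_changes(cm, default_contrasts(design), factors=np.ones(len(cm.sample_ids)))
        hits = total = 0
        for cond, genes in truth.de_lfc.items():
            for g, planted in genes.items():
                total += 1
                hits += abs(lfc.loc[g, cond] - planted) <= 0.15
        assert total >= 300
        assert hits / total >= 0.95

    def test_marginal_means_match_model(self):
        design = gen_design(timepoints=("D0", "D4"))
        cm, _ = gen_counts(design, n_genes=10_000, de_spec=DESpec(frac_de=0.0, shift_frac=0.0),
                           dispersion=0.05, size_factor_range=(1.0, 1.0),
                           mean_log_median=100.0, mean_log_sigma=0.0, seed=5)
        observed = cm.counts.mean(axis=0)
        np.testing.assert_allclose(observed, 100.0, rtol=0.02)

    def test_false_positive_rate_without_planting(self):
        design = gen_design(timepoints=("D0", "D4", "D9"))
        cm, _ = gen_counts(design, n_genes=3000, de_spec=DESpec(frac_de=0.0, shift_frac=0.0),
                           dispersion=0.05, min_mean=100.0, mean_log_median=400.0,
                           mean_log_sigma=1.0, seed=8)
        lfc = log2_fold_changes(cm, default_contrasts(design))
        profile = call_de(lfc, threshold=1.0)
        assert profile.is_de.to_numpy().mean() < 0.10


class TestGenTerms:
    def test_planted_fold_arithmetic(self):
        universe = [f"g{i}" for i in range(1000)]
        target = universe[:100]
        _, truth = gen_terms(universe, n_terms=5, planted=(target, 0.3, 0.05), seed=0)
        assert truth["true_fold"] == pytest.approx(6.0)

    def test_all_terms_subsets_of_universe(self):
        universe = {f"g{i}" for i in range(200)}
        terms, _ = gen_terms(universe, n_terms=10, seed=1)
        assert all(genes <= universe for _, (_, genes) in terms.terms.items())

    def test_emitted_fold_matches_analytic_expectation(self):
        """E is attenuated below the planted coverage fold because the target
        itself contributes to the background term frequency; the analytic value
        is cov_t / ((cov_t*|T| + cov_b*(N-|T|)) / N), approaching the planted
        fold as |T|/N -> 0."""
        universe = [f"g{i}" for i in range(10_000)]
        rng = np.random.default_rng(9)
        target = list(rng.choice(universe, size=100, replace=False))
        terms, truth = gen_terms(universe, n_terms=1, planted=(target, 0.3, 0.05), seed=10)
        df = enrich(set(target), set(universe), terms, min_b=1)
        row = df[df["term"] == truth["planted_term"]].iloc[0]
        n_t, n_b = truth["n_in_target"], truth["n_in_background"]
        analytic = (n_t / 100) / ((n_t + n_b) / 10_000)
        assert row["E"] == pytest.approx(analytic, rel=1e-12)
        assert row["E"] == pytest.approx(6.0, rel=0.2)  # |T|/N = 1% attenuates mildly

    def test_planted_term_recovered_as_top_hit(self):
        universe = [f"g{i}" for i in range(2000)]
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            target = list(rng.choice(universe, size=150, replace=False))
            terms, truth = gen_terms(universe, n_terms=30, planted=(target, 0.3, 0.05),
                                     seed=200 + rep)
            df = enrich(set(target), set(universe), terms, min_b=3)
            hits += df.iloc[0]["term"] == truth["planted_term"]
        assert hits >= 19


class TestWriteDataset:
    def test_dataset_files_written_and_readable(self, tmp_path, tiny_design):
        from denet.enrichment import read_gmt
        from denet.expression import StudyDesign, read_counts
        from denet.pathways import PathwayCollection

        cm, truth = gen_counts(tiny_design, n_genes=200, seed=1)
        net = gen_scale_free(50, 2, seed=2)
        pws = gen_pathway_cover(net, n_pathways=4, seed=3)
        terms, _ = gen_terms(sorted(net.graph.nodes), n_terms=3, seed=4)
        paths = write_dataset(tmp_path, tiny_design, cm, truth, pws, terms)
        assert read_counts(paths["counts"]).shape == cm.shape
        assert len(StudyDesign.read(paths["design"]).sample_ids) == 7
        assert len(PathwayCollection.from_manifest(paths["pathway_manifest"])) == len(pws)
        assert len(read_gmt(paths["gmt"])) == 3
        assert "shifted_genes" in paths["truth"].read_text()


class TestNoiseFreeShiftRecovery:
    def test_truth_collection_recovers_planted_shift_exactly(self, tiny_design):
        _, truth = gen_counts(tiny_design, n_genes=800,
                              de_spec=DESpec(frac_de=0.1, shift_frac=0.2), seed=13)
        coll = truth.to_set_collection()
        res = temporal_shift_fraction(coll)
        assert res.shifted_genes == truth.shifted_genes
        assert res.denominator_genes == truth.high_dose_nonfinal_genes
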