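"""The synthetic-data generators: determinism, structure, planted signals."""

import numpy as np
import pandas as pd
import pytest

from saltscreen import deg, fuzzy, germination, network, simulate


class TestConfigValidation:
    def test_bad_census_days_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimConfig(census_days=(2, 4, 4, 8))

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimConfig(tolerant_fraction=1.5)

    def test_nonpositive_salt_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimConfig(salt_levels=(0.13, 0.0))


class TestGerminationGenerator:
    def test_deterministic(self, small_config):
        a, ca = simulate.generate_germination(small_config)
        b, cb = simulate.generate_germination(small_config)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_series_equal(ca, cb)

    def test_censuses_monotone_and_bounded(self, small_config):
        census, _ = simulate.generate_germination(small_config)
        for _, dish in census.groupby(["accession", "condition", "replicate"]):
            g = dish.sort_values("day")["germinated"].to_numpy()
            assert np.all(np.diff(g) >= 0)
            assert g[-1] <= small_config.n_seeds_per_dish

    def test_zero_salt_probability_means_no_salt_germination(self):
        cfg = simulate.SimConfig(seed=2, n_accessions=10,
                                 tolerant_salt_retention=0.0,
                                 sensitive_salt_retention=0.0,
                                 retention_sd=0.0)
        census, _ = simulate.generate_germination(cfg)
        assert (census.loc[census["condition"] == "salt", "germinated"] == 0).all()

    def test_tolerant_accessions_keep_more_salt_germination(self, small_config):
        census, classes = simulate.generate_germination(small_config)
        final = census[census["day"] == max(small_config.census_days)]
        rate = (final.groupby(["accession", "condition"])["germinated"].mean()
                .unstack())
        ratio = (rate["salt"] / rate["control"]).groupby(classes).mean()
        assert ratio["tolerant"] > ratio["sensitive"]

    def test_germination_screen_separates_latent_classes(self):
        """Top half by comprehensive score holds >= 80% of latent-tolerant
        accessions at the panel's class separation."""
        cfg = simulate.SimConfig(seed=1, n_accessions=104, tolerant_fraction=0.2)
        census, classes = simulate.generate_germination(cfg)
        rel = germination.relative_traits(germination.germination_traits(census))
        rel["group"] = "salt"
        out = fuzzy.evaluate(rel).set_index("accession")
        top_half = set(out.nsmallest(len(out) // 2, "total_rank").index)
        tolerant = set(classes.index[classes == "tolerant"])
        assert len(tolerant & top_half) / len(tolerant) >= 0.8


class TestCountsGenerator:
    def test_deterministic(self, small_config):
        a = simulate.generate_counts(small_config)
        b = simulate.generate_counts(small_config)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(pd.DataFrame(x), pd.DataFrame(y))

    def test_zero_deg_fraction(self, small_config):
        _, _, truth = simulate.generate_counts(
            small_config.with_(deg_fraction=0.0))
        assert (truth["direction"] == "none").all()

    def test_planted_recovery_at_strong_effect(self):
        """Pipeline recovers >= 95% of planted DEGs at near-zero dispersion
        and a 4-unit log2 effect."""
        recs = []
        for seed in range(1, 6):
            cfg = simulate.SimConfig(seed=seed, n_genes=2000, deg_fraction=0.05,
                                     lfc_effect=4.0, nb_dispersion=1e-9)
            counts, _, truth = simulate.generate_counts(cfg)
            cond = pd.Series({c: c.split("_")[0] for c in counts.columns})
            calls = deg.call_degs(deg.de_test(counts, cond, ("S", "C")))
            planted = truth.index[truth["direction"] != "none"]
            recs.append((calls.loc[planted, "call"] != "ns").mean())
        assert np.mean(recs) >= 0.95

    def test_nb_moment_check(self):
        """Equal baselines, no effects: the pooled empirical mean sits
        within 3 standard errors of the configured baseline, and per-gene
        means stay within 3 SE at close to the nominal rate."""
        mu, alpha = 200.0, 0.05
        cfg = simulate.SimConfig(seed=4, n_genes=5000, deg_fraction=0.0,
                                 nb_dispersion=alpha)
        counts, _, _ = simulate.generate_counts(cfg, baseline_mean=mu)
        x = counts.to_numpy(dtype=float)
        se_pooled = np.sqrt((mu + alpha * mu ** 2) / x.size)
        assert abs(x.mean() - mu) <= 3 * se_pooled
        se_gene = np.sqrt((mu + alpha * mu ** 2) / x.shape[1])
        outside = np.abs(x.mean(axis=1) - mu) > 3 * se_gene
        assert outside.mean() < 0.01

    def test_gene_lengths_in_range(self, small_config):
        _, lengths, _ = simulate.generate_counts(small_config)
        assert lengths.between(200, 10000).all()

    def test_small_gene_count_rejected(self, small_config):
        with pytest.raises(ValueError):
            simulate.generate_counts(small_config.with_(n_genes=50))


class TestAnnotationGenerator:
    def test_exact_term_size(self, small_config):
        genes = [f"g{i}" for i in range(100)]
        tm, _ = simulate.generate_annotations(
            small_config.with_(genes_per_term=(5, 5)), genes)
        assert all(len(g) == 5 for g in tm["genes"])

    def test_deterministic(self, small_config):
        genes = [f"g{i}" for i in range(100)]
        t1, f1 = simulate.generate_annotations(small_config, genes)
        t2, f2 = simulate.generate_annotations(small_config, genes)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_one_family_per_gene_from_catalogue(self, small_config):
        _, tf = simulate.generate_annotations(small_config,
                                              [f"g{i}" for i in range(500)])
        assert tf["gene"].is_unique
        assert set(tf["family"]) <= set(simulate.TF_FAMILIES)

    def test_empty_gene_ids_rejected(self, small_config):
        with pytest.raises(ValueError):
            simulate.generate_annotations(small_config, [])


class TestPpiGenerator:
    def test_deterministic(self, small_config):
        genes = [f"g{i}" for i in range(100)]
        pd.testing.assert_frame_equal(simulate.generate_ppi(small_config, genes),
                                      simulate.generate_ppi(small_config, genes))

    def test_no_background_leaves_exactly_planted_cliques(self):
        cfg = simulate.SimConfig(seed=6, ppi_nodes=40,
                                 planted_clique_sizes=(6, 4),
                                 background_edge_prob=0.0)
        edges = simulate.generate_ppi(cfg, [f"g{i}" for i in range(60)])
        g = network.build_graph(edges, 0.9)
        sizes = sorted(len(c) for c in network.maximal_cliques(g))
        assert sizes == [4, 6]
        assert g.number_of_edges() == 6 * 5 // 2 + 4 * 3 // 2

    def test_background_confidence_below_threshold(self, small_config):
        edges = simulate.generate_ppi(small_config,
                                      [f"g{i}" for i in range(80)])
        assert edges["confidence"].between(0, 1).all()

    def test_too_many_nodes_rejected(self, small_config):
        with pytest.raises(ValueError):
            simulate.generate_ppi(small_config, ["only", "three", "genes"])

    def test_hub_scores_match_planted_structure(self):
        """A planted 5-clique with no background yields the (5-1)! score for
        every member after thresholding."""
        cfg = simulate.SimConfig(seed=8, ppi_nodes=20,
                                 planted_clique_sizes=(5,),
                                 background_edge_prob=0.0)
        edges = simulate.generate_ppi(cfg, [f"g{i}" for i in range(30)])
        g = network.build_graph(edges, 0.9)
        s = network.mcc_scores(g)
        assert (s["mcc"] == 24).sum() == 5


class TestSubstreamIndependence:
    def test_streams_do_not_perturb_each_other(self, small_config):
        census1, _ = simulate.generate_germination(small_config)
        # interleave another generator; germination output must not change
        simulate.generate_counts(small_config)
        census2, _ = simulate.generate_germination(small_config)
        pd.testing.assert_frame_equal(census1, census2)
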