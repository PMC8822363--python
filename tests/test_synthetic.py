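"""Planted-truth generators: activations, triplets, paired outcomes, images."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from depictrsa import (
    GroundTruthSimilarity,
    ImageConfig,
    SyntheticConfig,
    cross_depiction_profile,
    generate_activations,
    generate_images,
    generate_paired_outcomes,
    generate_triplet_trials,
    planted_similarity,
)


class TestConfigValidation:
    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError, match="shared fraction"):
            SyntheticConfig(layers={"l": 8}, shared_fraction=(1.5,))

    def test_alpha_count_must_match_layers(self):
        with pytest.raises(ValueError, match="one alpha per layer"):
            SyntheticConfig(layers={"a": 8, "b": 8}, shared_fraction=(0.5,))

    def test_manmade_within_objects(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_objects=5, n_manmade=6, layers={"l": 8}, shared_fraction=(0.5,))

    def test_default_design_constants(self):
        cfg = SyntheticConfig()
        assert cfg.n_objects == 42 and cfg.n_manmade == 21
        assert cfg.depictions == ("photo", "drawing", "sketch")
        assert len(cfg.metadata()) == 126


class TestGenerateActivations:
    def test_bit_reproducible(self, small_config):
        m1 = generate_activations(small_config)
        m2 = generate_activations(small_config)
        for layer in m1.layer_names:
            np.testing.assert_array_equal(m1[layer].data, m2[layer].data)

    def test_alpha_zero_null_cross_correlation(self):
        """Independent idiosyncratic latents imply no cross-depiction
        correlation on average over seeds."""
        rhos = []
        for seed in range(50):
            cfg = SyntheticConfig(
                n_objects=12,
                n_manmade=6,
                layers={"l": 64},
                shared_fraction=(0.0,),
                noise_sd=0.05,
                class_signal=0.0,
                seed=seed,
            )
            prof = cross_depiction_profile(generate_activations(cfg))
            rhos.append(prof.rho.loc["l", "photo-drawing"])
        assert abs(np.mean(rhos)) < 0.05

    def test_recovered_correlation_monotone_in_alpha(self):
        """Mean cross-depiction rho increases over an alpha grid."""
        grid = (0.0, 0.25, 0.5, 0.75, 1.0)
        means = []
        for alpha in grid:
            rhos = []
            for seed in range(10):
                cfg = SyntheticConfig(
                    n_objects=20,
                    n_manmade=10,
                    depictions=("photo", "drawing"),
                    layers={"l": 96},
                    shared_fraction=(alpha,),
                    noise_sd=0.05,
                    seed=seed,
                )
                prof = cross_depiction_profile(generate_activations(cfg))
                rhos.append(prof.rho.loc["l", "photo-drawing"])
            means.append(np.mean(rhos))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_row_order_shared_across_layers(self, small_multi):
        metas = [small_multi[l].metadata for l in small_multi.layer_names]
        for m in metas[1:]:
            pd.testing.assert_frame_equal(m, metas[0])

    def test_save_load_roundtrip(self, small_multi, tmp_path):
        from depictrsa import MultiLayerActivationSet

        small_multi.save(tmp_path / "acts")
        loaded = MultiLayerActivationSet.load(tmp_path / "acts")
        assert loaded.layer_names == small_multi.layer_names
        for layer in loaded.layer_names:
            np.testing.assert_array_equal(loaded[layer].data, small_multi[layer].data)


class TestTripletSimulator:
    def test_unique_argmin_always_chosen(self):
        sim = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        gt = GroundTruthSimilarity(["x", "y", "z"], sim)
        trials = generate_triplet_trials(gt, mode="sampled", n_trials=50, seed=0)
        assert (trials.trials["chosen"] == "z").all()

    def test_exhaustive_covers_each_triple_once(self):
        rng = np.random.default_rng(1)
        n = 7
        vals = rng.uniform(0, 1, (n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        labels = [f"o{i}" for i in range(n)]
        trials = generate_triplet_trials(GroundTruthSimilarity(labels, vals), seed=2)
        assert len(trials) == len(list(combinations(range(n), 3)))
        seen = {
            frozenset(row)
            for row in trials.trials[["object_a", "object_b", "object_c"]].to_numpy()
        }
        assert len(seen) == len(trials)

    def test_tie_breaking_uniform(self):
        """With all similarities equal every object is chosen ~1/3."""
        n = 6
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, 1.0)
        labels = [f"o{i}" for i in range(n)]
        trials = generate_triplet_trials(
            GroundTruthSimilarity(labels, vals), mode="sampled", n_trials=3000, seed=3
        )
        freqs = trials.trials["chosen"].value_counts(normalize=True)
        # each object appears in a random third of trials; conditional on
        # appearing it should be chosen 1/3 of the time
        counts_present = {l: 0 for l in labels}
        for row in trials.trials[["object_a", "object_b", "object_c"]].to_numpy():
            for l in row:
                counts_present[l] += 1
        for label in labels:
            chosen = (trials.trials["chosen"] == label).sum()
            assert chosen / counts_present[label] == pytest.approx(1 / 3, abs=0.05)

    def test_softmax_prefers_dissimilar(self):
        sim = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]])
        gt = GroundTruthSimilarity(["x", "y", "z"], sim)
        trials = generate_triplet_trials(
            gt, mode="sampled", n_trials=400, choice_model="softmax",
            temperature=0.2, seed=4,
        )
        frac_z = (trials.trials["chosen"] == "z").mean()
        assert frac_z > 0.6

    def test_fewer_than_three_objects(self):
        gt = GroundTruthSimilarity(["a", "b"], np.eye(2) * 0 + np.array([[1, 0.5], [0.5, 1]]))
        with pytest.raises(ValueError):
            generate_triplet_trials(gt)


class TestPairedOutcomes:
    def test_perfect_marginals_no_discordance(self):
        t = generate_paired_outcomes(100, 1.0, 1.0, "independent", seed=0)
        assert t.discordant == (0, 0)
        assert t.a.all() and t.b.all()

    def test_maximal_concordance_equal_marginals(self):
        t = generate_paired_outcomes(500, 0.8, 0.8, "maximal", seed=1)
        assert t.discordant == (0, 0)

    def test_independence_matches_expected_cells(self):
        n = 4000
        t = generate_paired_outcomes(n, 0.7, 0.5, "independent", seed=2)
        assert t.a.mean() == pytest.approx(0.7, abs=0.03)
        assert t.b.mean() == pytest.approx(0.5, abs=0.03)
        b10, b01 = t.discordant
        assert b10 / n == pytest.approx(0.7 * 0.5, abs=0.03)  # p_a(1-p_b)=0.35
        assert b01 / n == pytest.approx(0.3 * 0.5, abs=0.03)

    def test_infeasible_concordance_states_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            generate_paired_outcomes(10, 0.9, 0.1, concordance=0.95)

    def test_deterministic_given_seed(self):
        t1 = generate_paired_outcomes(50, 0.6, 0.4, "independent", seed=3)
        t2 = generate_paired_outcomes(50, 0.6, 0.4, "independent", seed=3)
        np.testing.assert_array_equal(t1.a, t2.a)
        np.testing.assert_array_equal(t1.b, t2.b)


class TestGenerateImages:
    def test_variants_share_vertices(self):
        imset = generate_images(ImageConfig(n_objects=4, seed=0))
        for obj in imset.images:
            assert imset.vertices[obj].shape[1] == 2
        # determinism: same seed, same vertices
        again = generate_images(ImageConfig(n_objects=4, seed=0))
        for obj in imset.vertices:
            np.testing.assert_array_equal(imset.vertices[obj], again.vertices[obj])

    def test_contour_mostly_background(self):
        cfg = ImageConfig(n_objects=4, seed=1)
        imset = generate_images(cfg)
        for obj, variants in imset.images.items():
            contour = variants["contour"]
            bg_frac = np.mean(np.all(contour == cfg.background, axis=2))
            assert bg_frac >= 0.8

    def test_textured_has_substantial_foreground(self):
        cfg = ImageConfig(n_objects=4, seed=2)
        imset = generate_images(cfg)
        for variants in imset.images.values():
            fg = np.mean(np.any(variants["textured"] != cfg.background, axis=2))
            assert fg > 0.1

    def test_different_seeds_different_shapes(self):
        a = generate_images(ImageConfig(n_objects=3, seed=0))
        b = generate_images(ImageConfig(n_objects=3, seed=99))
        obj = next(iter(a.vertices))
        assert not np.array_equal(a.vertices[obj], b.vertices[obj])

    def test_degenerate_canvas_rejected(self):
        with pytest.raises(ValueError, match="canvas"):
            ImageConfig(canvas=8)

    def test_png_roundtrip(self, tmp_path):
        imset = generate_images(ImageConfig(n_objects=2, seed=5))
        imset.save(tmp_path)
        assert len(list(tmp_path.glob("*.png"))) == 4


class TestPlantedSimilarity:
    def test_valid_similarity_matrix(self):
        sim = planted_similarity(SyntheticConfig(n_objects=8, n_manmade=4,
                                                 layers={"l": 16}, shared_fraction=(0.5,)))
        assert np.allclose(np.diag(sim.values), 1.0)
        assert np.allclose(sim.values, sim.values.T)
        assert sim.values.min() >= 0.0 and sim.values.max() <= 1.0
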