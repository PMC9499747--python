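"""GA clustering primitives against brute-force oracles, and full-GA recovery."""

import numpy as np
import pytest

from gliopipe import GAClusterSegmenter, GAConfig, run_ga
from gliopipe.ga_segment import (
    assign_clusters,
    clustering_metric,
    crossover,
    fitness,
    mutate,
    roulette_select,
    update_centres,
)


# ------------------------------------------------------------------ oracles

def brute_assign(pixels, centres):
    """Exhaustive nearest-centre search, lowest index on ties."""
    return np.array([
        min(range(len(centres)), key=lambda j: (abs(p - centres[j]), j))
        for p in pixels
    ])


def brute_metric(pixels, labels, centres):
    """Double loop over clusters and members."""
    total = 0.0
    for j, z in enumerate(centres):
        for p, lab in zip(pixels, labels):
            if lab == j:
                total += abs(p - z)
    return total


def brute_means(pixels, labels, k, prev):
    out = []
    for j in range(k):
        members = [p for p, lab in zip(pixels, labels) if lab == j]
        out.append(np.mean(members) if members else prev[j])
    return np.array(out)


class TestAssignClusters:
    def test_nearest_centre_example(self):
        labels = assign_clusters([0.0, 10.0], [1.0, 9.0])
        np.testing.assert_array_equal(labels, [0, 1])

    def test_single_centre_takes_all(self, rng):
        labels = assign_clusters(rng.uniform(0, 255, 50), [100.0])
        assert np.all(labels == 0)

    def test_empty_pixel_list(self):
        assert assign_clusters([], [1.0, 2.0]).size == 0

    def test_no_centres_rejected(self):
        with pytest.raises(ValueError):
            assign_clusters([1.0], [])

    def test_midpoint_tie_broken_at_random(self):
        """Pixel equidistant from both centres: each side ~50% of trials."""
        counts = np.zeros(2)
        for s in range(10_000):
            lab = assign_clusters([5.0], [0.0, 10.0],
                                  rng=np.random.default_rng(s))
            counts[lab[0]] += 1
        assert abs(counts[0] / 10_000 - 0.5) < 0.02

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 101))
            k = int(rng.integers(1, 4))
            pixels = rng.uniform(0, 255, n)
            centres = rng.uniform(0, 255, k)
            got = assign_clusters(pixels, centres)
            np.testing.assert_array_equal(got, brute_assign(pixels, centres))


class TestUpdateCentres:
    def test_mean_of_members(self):
        got = update_centres([2.0, 4.0], [0, 0], 1)
        assert got[0] == pytest.approx(3.0)

    def test_all_equal_pixels(self):
        got = update_centres([7.0] * 10, [0] * 10, 2, prev_centres=[7.0, 50.0])
        assert got[0] == pytest.approx(7.0)
        assert got[1] == pytest.approx(50.0)  # empty cluster keeps previous

    def test_fixed_point_at_cluster_means(self, rng):
        pixels = rng.uniform(0, 255, 60)
        centres = np.array([50.0, 200.0])
        labels = assign_clusters(pixels, centres)
        means = update_centres(pixels, labels, 2, prev_centres=centres)
        again = update_centres(pixels, assign_clusters(pixels, means), 2,
                               prev_centres=means)
        twice = update_centres(pixels, assign_clusters(pixels, again), 2,
                               prev_centres=again)
        np.testing.assert_allclose(twice, again, atol=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 101))
            k = int(rng.integers(1, 4))
            pixels = rng.uniform(0, 255, n)
            labels = rng.integers(0, k, n)
            prev = rng.uniform(0, 255, k)
            got = update_centres(pixels, labels, k, prev_centres=prev)
            np.testing.assert_allclose(got, brute_means(pixels, labels, k, prev),
                                       atol=1e-10)


class TestClusteringMetric:
    def test_zero_when_pixels_sit_on_centres(self):
        assert clustering_metric([5.0, 9.0], [0, 1], [5.0, 9.0]) == 0.0

    def test_hand_example(self):
        assert clustering_metric([0.0, 10.0], [0, 0], [5.0]) == pytest.approx(10.0)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 101))
            k = int(rng.integers(1, 4))
            pixels = rng.uniform(0, 255, n)
            centres = rng.uniform(0, 255, k)
            labels = assign_clusters(pixels, centres)
            assert clustering_metric(pixels, labels, centres) == pytest.approx(
                brute_metric(pixels, labels, centres), abs=1e-10)


class TestFitness:
    def test_strictly_decreasing_in_metric(self):
        assert fitness(3.0) > fitness(4.0) > fitness(100.0)

    def test_zero_metric_is_finite(self):
        assert np.isfinite(fitness(0.0))
        assert fitness(0.0) == pytest.approx(1e9)

    def test_reciprocal_limit(self):
        assert fitness(4.0, eps=0.0) == pytest.approx(0.25)

    def test_negative_metric_rejected(self):
        with pytest.raises(ValueError):
            fitness(-1.0)


class TestRouletteSelect:
    def test_equal_fitness_is_uniform(self):
        rng = np.random.default_rng(0)
        picks = roulette_select([1.0, 1.0], rng, size=20_000)
        assert abs(np.mean(picks == 0) - 0.5) < 0.02

    def test_three_to_one_ratio(self):
        rng = np.random.default_rng(1)
        picks = roulette_select([3.0, 1.0], rng, size=20_000)
        assert abs(np.mean(picks == 0) - 0.75) < 0.02

    def test_single_member_always_selected(self):
        rng = np.random.default_rng(2)
        assert np.all(roulette_select([2.5], rng, size=5) == 0)

    def test_all_zero_fitness_warns_and_uniform(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="uniform"):
            picks = roulette_select([0.0, 0.0], rng, size=100)
        assert set(picks) == {0, 1}


class TestMutate:
    def _cfg(self, **kw):
        return GAConfig(**{"mutation_prob": 1.0, "max_generations": 100, **kw})

    def test_final_generation_leaves_genes_unchanged(self):
        rng = np.random.default_rng(0)
        cfg = self._cfg()
        x = np.array([10.0, 200.0])
        got = mutate(x, (0.0, 255.0), cfg.max_generations, cfg, rng)
        np.testing.assert_array_equal(got, x)

    def test_gene_at_upper_bound_cannot_move_up(self):
        cfg = self._cfg()
        for s in range(200):
            rng = np.random.default_rng(s)
            p_l = np.random.default_rng(s)
            got = mutate([255.0], (0.0, 255.0), 1, cfg, rng)
            assert got[0] <= 255.0

    def test_results_always_within_bounds(self):
        cfg = self._cfg()
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            gen = int(rng.integers(0, cfg.max_generations + 1))
            got = mutate([128.0], (0.0, 255.0), gen, cfg, rng)
            assert 0.0 <= got[0] <= 255.0


class TestCrossover:
    def test_identity_at_a_equals_one(self, rng):
        m, n = rng.uniform(0, 255, 3), rng.uniform(0, 255, 3)
        m2, n2 = crossover(m, n, a=1.0)
        np.testing.assert_array_equal(m2, m)
        np.testing.assert_array_equal(n2, n)

    def test_midpoint_at_half(self):
        m2, n2 = crossover([0.0, 10.0], [10.0, 30.0], a=0.5)
        np.testing.assert_allclose(m2, [5.0, 20.0])
        np.testing.assert_allclose(n2, m2)

    @pytest.mark.parametrize("a", [0.0, 0.3, 0.5, 0.9, 1.0])
    def test_gene_sums_preserved(self, a, rng):
        m, n = rng.uniform(0, 255, 5), rng.uniform(0, 255, 5)
        m2, n2 = crossover(m, n, a=a)
        np.testing.assert_allclose(m2 + n2, m + n, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossover([1.0], [1.0, 2.0], a=0.5)


class TestRunGA:
    def test_two_value_image_recovery(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < 0.9, 40.0, 200.0)
        seg = run_ga(img, GAConfig(n_clusters=2, seed=1))
        np.testing.assert_allclose(np.sort(seg.centres), [40.0, 200.0], atol=2.0)

    def test_best_metric_never_worse_than_initial_best(self, rng):
        """Elitism: the final M cannot exceed any generation-1 best."""
        img = rng.uniform(0, 255, (32, 32))
        seg = run_ga(img, GAConfig(n_clusters=3, seed=4, max_generations=30))
        first_best_m = seg.history[0][1]
        assert seg.metric <= first_best_m + 1e-9

    def test_best_fitness_nondecreasing_over_generations(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        seg = run_ga(img, GAConfig(n_clusters=3, seed=5, max_generations=25))
        fits = [f for _, _, f in seg.history]
        assert np.all(np.diff(fits) >= -1e-15)

    def test_too_many_clusters_rejected(self):
        img = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 10.0, 20.0)
        with pytest.raises(ValueError, match="distinct intensities"):
            run_ga(img, GAConfig(n_clusters=3, seed=0))

    def test_tumor_mask_is_single_brightest_cluster(self, small_phantom):
        seg = run_ga(small_phantom.image,
                     GAConfig(n_clusters=3, seed=2, max_generations=30,
                              clean_mask=False),
                     brain_mask=small_phantom.brain_mask)
        inside = seg.labels[small_phantom.brain_mask]
        assert set(np.unique(inside)) <= {0, 1, 2}
        assert np.all(seg.labels[~small_phantom.brain_mask] == -1)
        tumor_label = np.unique(seg.labels[seg.tumor_mask])
        assert tumor_label.size == 1

    def test_sklearn_estimator_surface(self, rng):
        X = rng.uniform(0, 255, (500, 1))
        est = GAClusterSegmenter(n_clusters=3, max_generations=15,
                                 random_state=0).fit(X)
        assert est.cluster_centers_.shape == (3,)
        assert np.all(np.diff(est.cluster_centers_) >= 0)
        pred = est.predict(X[:10])
        assert pred.shape == (10,)
        params = est.get_params()
        assert params["n_clusters"] == 3
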