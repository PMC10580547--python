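import numpy as np
import pandas as pd
import pytest

from motorage.lda import (
    GAConfig,
    PUBLISHED_AXIS,
    evaluate_published_axis,
    evolve_generation,
    init_population,
    normalize_columns,
    project_lda_value,
    relevance_filter,
    run_ga,
    separability_ez,
    to_hyperspherical,
)

TWO_PI = 2 * np.pi


class TestNormalization:
    def test_range_with_offset(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        np.testing.assert_allclose(normalize_columns(df)["a"], [0.1, 0.6, 1.1])

    def test_endpoints_exact(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        C = normalize_columns(df)
        np.testing.assert_allclose(C.min(axis=0), 0.1)
        np.testing.assert_allclose(C.max(axis=0), 1.1)

    def test_constant_column_maps_to_offset(self):
        df = pd.DataFrame({"a": [7.0, 7.0, 7.0], "b": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(normalize_columns(df)["a"], 0.1)


class TestHyperspherical:
    def test_two_dimensional_example(self):
        p, theta = to_hyperspherical(np.array([3.0, 4.0]))
        assert p == pytest.approx(5.0)
        assert theta[0] == pytest.approx(np.arctan(4 / 3), abs=1e-5)

    def test_three_dimensional_example(self):
        p, theta = to_hyperspherical(np.array([1.0, 1.0, 1.0]))
        assert p == pytest.approx(np.sqrt(3.0))
        assert theta[0] == pytest.approx(np.pi / 4)
        assert theta[1] == pytest.approx(np.arctan(1 / np.sqrt(2)), abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_identity(self, seed):
        c = np.random.default_rng(seed).uniform(0.1, 1.1, size=8)
        p, theta = to_hyperspherical(c)
        assert p * np.prod(np.cos(theta)) == pytest.approx(c[0], abs=1e-9)

    def test_angles_in_first_quadrant_for_positive_input(self, rng):
        C = rng.uniform(0.1, 1.1, size=(20, 6))
        _, theta = to_hyperspherical(C)
        assert ((theta > 0) & (theta < np.pi / 2)).all()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            to_hyperspherical(np.array([1.0, 0.0]))


class TestProjection:
    def test_identity_rotation_returns_first_coordinate(self):
        p, theta = to_hyperspherical(np.array([3.0, 4.0]))
        assert project_lda_value(p, theta, np.zeros(1)) == pytest.approx(3.0)

    def test_alignment_returns_radius(self):
        p, theta = to_hyperspherical(np.array([3.0, 4.0]))
        assert project_lda_value(p, theta, -theta) == pytest.approx(5.0)

    def test_orthogonality_returns_zero(self):
        p, theta = to_hyperspherical(np.array([3.0, 4.0]))
        assert project_lda_value(p, theta, np.pi / 2 - theta) == pytest.approx(0.0, abs=1e-12)

    def test_batched_axes_match_loop(self, rng):
        C = rng.uniform(0.1, 1.1, size=(7, 5))
        p, theta = to_hyperspherical(C)
        axes = rng.uniform(0, TWO_PI, size=(4, 4))
        batch = project_lda_value(p, theta, axes)
        for i in range(4):
            np.testing.assert_allclose(batch[i], project_lda_value(p, theta, axes[i]))


class TestSeparability:
    def test_worked_two_group_case(self):
        values = np.array([-1.0, 1.0, 2.0, 4.0])
        groups = np.array([1, 1, 2, 2])
        assert separability_ez(values, groups) == pytest.approx(3 / np.sqrt(2))

    def test_identical_groups_zero(self):
        values = np.array([1.0, 2.0, 1.0, 2.0])
        assert separability_ez(values, np.array([1, 1, 2, 2])) == pytest.approx(0.0)

    def test_three_groups_equal_pairwise_decomposition(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat([1, 2, 3], 10)
        total = separability_ez(values, groups)
        pair_sum = 0.0
        for a, b in [(1, 2), (1, 3), (2, 3)]:
            sel = np.isin(groups, [a, b])
            pair_sum += separability_ez(values[sel], groups[sel])
        assert total == pytest.approx(pair_sum)

    def test_shift_invariance_and_scale_equivariance(self, rng):
        values = rng.normal(size=40)
        groups = np.repeat([1, 2, 3, 4], 10)
        base = separability_ez(values, groups)
        assert separability_ez(values + 13.0, groups) == pytest.approx(base)
        assert separability_ez(-2.5 * values, groups) == pytest.approx(base)

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError):
            separability_ez(np.arange(3.0), np.array([1, 1, 2]))


class TestGeneticAlgorithm:
    def test_initial_population_range_seeded_and_sized(self):
        cfg = GAConfig()
        rng = np.random.default_rng(5)
        pop = init_population(cfg, 10, rng)
        assert pop.shape == (50, 10)  # default population of 50 axes
        assert ((pop >= 0) & (pop < TWO_PI)).all()
        pop2 = init_population(cfg, 10, np.random.default_rng(5))
        np.testing.assert_array_equal(pop, pop2)

    def test_arithmetic_children(self):
        # parents (0,0) and (2,2) -> children (-1,-1), (1,1), (3,3) pre-wrap
        p1, p2 = np.zeros(2), np.full(2, 2.0)
        children = np.stack([1.5 * p1 - 0.5 * p2, 0.5 * p1 + 0.5 * p2, -0.5 * p1 + 1.5 * p2])
        np.testing.assert_allclose(children, [[-1, -1], [1, 1], [3, 3]])
        wrapped = children % TWO_PI
        np.testing.assert_allclose(wrapped[0], TWO_PI - 1)

    def test_pure_selection_is_subset_of_population(self, rng):
        cfg = GAConfig(s=6, p_mutation=0.0, p_crossover=0.0)
        pop = init_population(cfg, 3, rng)
        fit = np.arange(1.0, 7.0)
        new, _ = evolve_generation(pop, fit, cfg, rng, lambda a: np.ones(len(a)))
        for row in new:
            assert any(np.allclose(row, old) for old in pop)

    def test_population_angles_stay_wrapped(self, rng):
        cfg = GAConfig(s=10, p_mutation=0.3, p_crossover=0.9)
        pop = init_population(cfg, 4, rng)
        fit = rng.uniform(1, 2, size=10)
        for _ in range(20):
            pop, fit = evolve_generation(pop, fit, cfg, rng, lambda a: np.abs(a).sum(axis=1))
            assert ((pop >= 0) & (pop < TWO_PI)).all()

    @staticmethod
    def _two_feature_problem():
        rng = np.random.default_rng(77)
        a = np.column_stack([rng.normal(1.0, 0.05, 20), rng.normal(0.3, 0.05, 20)])
        b = np.column_stack([rng.normal(0.3, 0.05, 20), rng.normal(1.0, 0.05, 20)])
        C = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2"])
        groups = np.repeat([1, 2], 20)
        return normalize_columns(C), groups

    def test_ga_matches_grid_search_on_single_angle(self):
        C, groups = self._two_feature_problem()
        p, theta = to_hyperspherical(C.to_numpy())
        grid = np.linspace(0, TWO_PI, 3600, endpoint=False)[:, None]
        ez_grid = np.array(
            [separability_ez(project_lda_value(p, theta, g), groups) for g in grid]
        )
        optimum = ez_grid.max()
        cfg = GAConfig(epochs=200, seed=3)
        res = run_ga(p, theta, groups, cfg)
        assert res.best_ez >= 0.99 * optimum

    def test_trace_monotone_under_elitism(self):
        C, groups = self._two_feature_problem()
        p, theta = to_hyperspherical(C.to_numpy())
        res = run_ga(p, theta, groups, GAConfig(epochs=100, seed=1))
        assert (np.diff(res.ez_trace) >= 0).all()

    def test_seeded_run_reproducible(self):
        C, groups = self._two_feature_problem()
        p, theta = to_hyperspherical(C.to_numpy())
        r1 = run_ga(p, theta, groups, GAConfig(epochs=50, seed=9))
        r2 = run_ga(p, theta, groups, GAConfig(epochs=50, seed=9))
        np.testing.assert_array_equal(r1.best_axis, r2.best_axis)
        np.testing.assert_array_equal(r1.projections, r2.projections)

    def test_label_permutation_collapses_separability(self):
        rng = np.random.default_rng(13)
        from motorage.cohort import CohortSpec, EffectModel, simulate_feature_matrix

        sim = simulate_feature_matrix(
            CohortSpec(seed=61),
            EffectModel(affected_fraction=1.0, slope_scale=0.03, noise_sd=0.2),
            n_features=10,
        )
        C = normalize_columns(sim.values)
        p, theta = to_hyperspherical(C.to_numpy())
        cfg = GAConfig(epochs=150, seed=2)
        structured = run_ga(p, theta, sim.groups.to_numpy(), cfg).best_ez
        permuted = run_ga(
            p, theta, rng.permutation(sim.groups.to_numpy()), cfg
        ).best_ez
        assert permuted < 0.25 * structured


class TestRelevanceFilter:
    def test_separating_feature_retained_among_noise(self):
        rng = np.random.default_rng(17)
        n = 40
        groups = np.repeat([1, 2], n // 2)
        strong = np.where(groups == 1, 0.2, 1.0) + rng.normal(0, 0.03, n)
        cols = {"strong": strong}
        for k in range(10):
            cols[f"noise{k}"] = rng.normal(size=n)
        C = normalize_columns(pd.DataFrame(cols))
        p, theta = to_hyperspherical(C.to_numpy())
        cfg = GAConfig(epochs=150, seed=4)
        res = run_ga(p, theta, groups, cfg)
        mask, relevance = relevance_filter(C, groups, res.best_axis, cfg)
        assert mask[0]
        assert relevance[0] == relevance.max()

    def test_all_separating_features_all_relevant(self):
        rng = np.random.default_rng(19)
        groups = np.repeat([1, 2], 15)
        base = np.where(groups == 1, 0.2, 1.0)
        C = normalize_columns(
            pd.DataFrame({f"f{k}": base + rng.normal(0, 0.02, 30) for k in range(4)})
        )
        p, theta = to_hyperspherical(C.to_numpy())
        cfg = GAConfig(epochs=150, seed=6)
        res = run_ga(p, theta, groups, cfg)
        mask, _ = relevance_filter(C, groups, res.best_axis, cfg)
        assert mask.all()


class TestPublishedAxis:
    def test_axis_has_46_offsets_and_labels(self):
        assert len(PUBLISHED_AXIS.offsets) == 46
        assert len(PUBLISHED_AXIS.feature_labels) == 46
        assert len(PUBLISHED_AXIS.feature_info) == 46

    def test_cancelling_angles_return_radius(self):
        theta = -np.asarray(PUBLISHED_AXIS.offsets)
        assert evaluate_published_axis(theta, 7.25) == pytest.approx(7.25)

    def test_zero_radius(self, rng):
        theta = rng.uniform(0, TWO_PI, size=46)
        assert evaluate_published_axis(theta, 0.0) == 0.0

    def test_matches_independent_product_loop(self, rng):
        theta = rng.uniform(0, TWO_PI, size=46)
        R = 3.7
        expected = R
        for t, off in zip(theta, PUBLISHED_AXIS.offsets):
            expected *= np.cos(t + off)
        assert evaluate_published_axis(theta, R) == pytest.approx(expected, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            evaluate_published_axis(np.zeros(45), 1.0)
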