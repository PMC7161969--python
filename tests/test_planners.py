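import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from autolab import analysis
from autolab.errors import (ConfigurationError, GridSizeError,
                            PreconditionError)
from autolab.planners import (BayesianPlanner, DoEPlanner, PlannerState,
                              acquisition_value, available_planners,
                              full_factorial_grid, make_planner,
                              propose_bayesian, propose_factorial,
                              propose_random, refine_subregion,
                              register_planner)
from autolab.space import ParameterSpace

from conftest import make_history


class TestRandom:
    def test_bounds_and_length(self, space5):
        x = propose_random(space5, PlannerState(kind="random"),
                           np.random.default_rng(0))
        assert x.shape == (5,)
        assert np.all((x >= 0) & (x <= 1))

    def test_same_seed_same_draw(self, space5):
        state = PlannerState(kind="random")
        a = propose_random(space5, state, np.random.default_rng(7))
        b = propose_random(space5, state, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_uniformity_ks(self):
        space = ParameterSpace(n_dims=1)
        rng = np.random.default_rng(3)
        draws = np.array([
            propose_random(space, PlannerState(kind="random"), rng)[0]
            for _ in range(10_000)
        ])
        assert stats.kstest(draws, "uniform").pvalue > 0.01


class TestFactorial:
    def test_3x3_grid(self, space2):
        grid = propose_factorial(space2, PlannerState(doe_levels=3), stage=1)
        assert grid.shape == (9, 2)
        for point in [(0, 0), (0.5, 0.5), (1, 1)]:
            assert any(np.allclose(row, point) for row in grid)

    def test_2_to_the_6(self):
        space = ParameterSpace(n_dims=6)
        grid = propose_factorial(space, PlannerState(doe_levels=2), stage=1)
        assert grid.shape == (64, 6)

    def test_grid_cap_error_reports_count(self):
        space = ParameterSpace(n_dims=8)
        with pytest.raises(GridSizeError) as exc:
            full_factorial_grid(space.bounds, 5, cap=1000)
        assert exc.value.n_points == 5 ** 8

    def test_stage2_requires_history(self, space2):
        with pytest.raises(PreconditionError):
            propose_factorial(space2, PlannerState(), stage=2)

    def test_stage2_around_center(self, space2, history_factory):
        history = history_factory(space2, [[0.5, 0.5], [0.9, 0.1]],
                                  [0.1, 0.9])
        grid = propose_factorial(space2, PlannerState(doe_levels=3),
                                 stage=2, history=history)
        assert grid.shape == (9, 2)
        assert grid.min() == pytest.approx(0.25)
        assert grid.max() == pytest.approx(0.75)

    def test_grids_are_deterministic(self, space2, history_factory):
        state = PlannerState(doe_levels=3)
        a = propose_factorial(space2, state, stage=1)
        b = propose_factorial(space2, state, stage=1)
        np.testing.assert_array_equal(a, b)


class TestRefineSubregion:
    def test_center(self, history_factory):
        space = ParameterSpace(n_dims=1)
        h = history_factory(space, [[0.5]], [0.0])
        assert refine_subregion(h, space) == ((0.25, 0.75),)

    def test_clip_at_lower_boundary(self, history_factory):
        space = ParameterSpace(n_dims=1)
        h = history_factory(space, [[0.0]], [0.0])
        # clip without re-centering: 0.0 +/- 0.25 -> [0, 0.25]
        assert refine_subregion(h, space) == ((0.0, 0.25),)

    def test_clip_near_upper_boundary(self, history_factory):
        space = ParameterSpace(n_dims=1)
        h = history_factory(space, [[0.9]], [0.0])
        lo, hi = refine_subregion(h, space)[0]
        assert lo == pytest.approx(0.65)
        assert hi == pytest.approx(1.0)

    def test_empty_history_rejected(self, space2):
        with pytest.raises(PreconditionError):
            refine_subregion(analysis.History(space2), space2)


class TestAcquisition:
    def test_empty_history_constant(self, space2):
        h = make_history(space2, [], [])
        state = PlannerState()
        vals = {acquisition_value([x, x], h, "exploit", state)
                for x in (0.1, 0.5, 0.9)}
        assert len(vals) == 1

    def test_exploit_minimum_near_observation(self):
        space = ParameterSpace(n_dims=1)
        h = make_history(space, [[0.4], [0.8], [0.1]], [0.0, 1.0, 1.0])
        state = PlannerState()
        grid = np.linspace(0, 1, 201)
        scores = [acquisition_value([g], h, "exploit", state) for g in grid]
        assert abs(grid[int(np.argmin(scores))] - 0.4) <= state.kernel_width

    def test_large_prior_weight_flattens_to_mean(self, space2):
        h = make_history(space2, [[0.2, 0.2], [0.8, 0.8]], [0.0, 1.0])
        state = replace(PlannerState(), w0_explore=1e9)
        fbar = 0.5
        for x in ([0.2, 0.2], [0.5, 0.5], [0.9, 0.1]):
            assert acquisition_value(x, h, "explore", state) == \
                pytest.approx(fbar, abs=1e-6)

    def test_invalid_mode_rejected(self, space2):
        h = make_history(space2, [[0.5, 0.5]], [0.1])
        with pytest.raises(ConfigurationError):
            acquisition_value([0.5, 0.5], h, "none", PlannerState())


def _sharp_history(seed, n=12):
    """Realistic converged history around a sharp 2-D minimum."""
    target = np.array([0.3, 0.7])
    surface = analysis.FunctionSurface(
        lambda x: float(min(1.0, 25 * ((x - target) ** 2).sum())), 2)
    return analysis.run_loop(surface, "bayesian", n, seed), target


class TestProposeBayesian:
    def test_empty_history_uniform(self, space5):
        h = make_history(space5, [], [])
        x, mode = propose_bayesian(space5, h, PlannerState(),
                                   np.random.default_rng(0), 0)
        assert np.all((x >= 0) & (x <= 1))
        assert mode == PlannerState().bias_schedule[0]

    def test_mode_follows_schedule(self, space5):
        h = make_history(space5, [], [])
        state = PlannerState(bias_schedule=("explore", "exploit"))
        for it, expected in [(0, "explore"), (1, "exploit"), (2, "explore")]:
            _, mode = propose_bayesian(space5, h, state,
                                       np.random.default_rng(0), it)
            assert mode == expected

    def test_exploit_proposals_near_sharp_minimum(self):
        hits = 0
        for seed in range(50):
            history, _ = _sharp_history(7000 + seed)
            incumbent = history.params_matrix()[
                int(np.argmin(history.objectives()))]
            x, _ = propose_bayesian(
                history.space, history,
                PlannerState(bias_schedule=("exploit",)),
                np.random.default_rng(seed), 0)
            if np.linalg.norm(x - incumbent) < 0.15:
                hits += 1
        assert hits / 50 >= 0.8

    def test_explore_farther_from_data_than_exploit(self):
        wins = 0
        for seed in range(50):
            history, _ = _sharp_history(7000 + seed)
            X = history.params_matrix()
            exploit, _ = propose_bayesian(
                history.space, history,
                PlannerState(bias_schedule=("exploit",)),
                np.random.default_rng(seed), 0)
            explore, _ = propose_bayesian(
                history.space, history,
                PlannerState(bias_schedule=("explore",)),
                np.random.default_rng(seed), 0)

            def nearest(p):
                return np.sqrt(((X - p) ** 2).sum(axis=1)).min()

            if nearest(explore) > nearest(exploit):
                wins += 1
        assert wins / 50 >= 0.8

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), it=st.integers(0, 10))
    def test_proposals_always_in_bounds(self, seed, it):
        space = ParameterSpace(n_dims=3)
        rng = np.random.default_rng(seed)
        h = make_history(space, rng.uniform(size=(6, 3)),
                         rng.normal(size=6),
                         modes=["exploit", "explore"] * 3)
        x, _ = propose_bayesian(space, h, PlannerState(), rng, it)
        assert np.all((x >= 0) & (x <= 1))


class TestPlannerOrdering:
    def test_bayesian_beats_random_on_sphere(self):
        surface = analysis.FunctionSurface(
            lambda x: float(((x - 0.5) ** 2).sum()), 5)
        result = analysis.benchmark_planners(
            surface, ["bayesian", "random"], budget=30, n_runs=20, seed=1)
        bayes = result.runs.query(
            "planner == 'bayesian' and iteration == 29")["best_so_far"]
        rand = result.runs.query(
            "planner == 'random' and iteration == 29")["best_so_far"]
        # one-sided Welch test at alpha = 0.05
        t = stats.ttest_ind(bayes, rand, equal_var=False,
                            alternative="less")
        assert t.pvalue < 0.05

    def test_alternating_bias_widens_distance_distribution(self):
        from autolab.characterization import make_objective, make_target
        from autolab.virtual_lab import HplcInstrument

        surface = analysis.InstrumentSurface(
            HplcInstrument(0.0),
            make_objective("hplc", make_target("hplc", None)))
        wins = 0
        for seed in range(1, 11):
            mixed = analysis.run_loop(surface, "bayesian", 50, seed)
            pure = analysis.run_loop(
                surface, "bayesian", 50, seed,
                PlannerState(bias_schedule=("exploit",)))
            if analysis.pairwise_distances(mixed).var() > \
                    analysis.pairwise_distances(pure).var():
                wins += 1
        assert wins >= 6


class TestDoEPlanner:
    def test_covers_budget_without_repeats(self, space2):
        planner = DoEPlanner(budget=10)
        h = make_history(space2, [], [])
        seen = []
        rng = np.random.default_rng(0)
        for i in range(5):  # stage 1
            x, mode = planner.propose(space2, h, i, rng)
            assert mode == "none"
            h.record(
                analysis.ProposalRequest(f"d-r{i}", "t", tuple(x),
                                         created_at=i),
                analysis.Observation(f"d-r{i}", float(((x - 0.5)**2).sum()),
                                     measured_at=i))
            seen.append(tuple(np.round(x, 9)))
        assert len(set(seen)) == 5

        # stage 2 lies inside the refined half-range box
        best = h.best()[0].params
        for i in range(5, 10):
            x, _ = planner.propose(space2, h, i, rng)
            for dim in range(2):
                assert x[dim] >= max(0.0, best[dim] - 0.25) - 1e-12
                assert x[dim] <= min(1.0, best[dim] + 0.25) + 1e-12


class TestRegistry:
    def test_available_planners(self):
        assert {"random", "doe", "bayesian"} <= set(available_planners())

    def test_unknown_planner_raises(self):
        with pytest.raises(ConfigurationError, match="registered planners"):
            make_planner("simplex", budget=10)

    def test_external_planner_plugs_in(self, space5):
        class Center:
            def propose(self, space, history, iteration, rng):
                return np.full(space.n_dims, 0.5), "none"

        register_planner("center", lambda budget, state: Center())
        try:
            planner = make_planner("center", budget=3)
            h = make_history(space5, [], [])
            x, _ = planner.propose(space5, h, 0, np.random.default_rng(0))
            np.testing.assert_allclose(x, 0.5)
        finally:
            from autolab import planners as planner_module
            planner_module._REGISTRY.pop("center", None)
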