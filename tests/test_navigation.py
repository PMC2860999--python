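"""Control maps, Dijkstra policies and closed-loop occupancy propagation."""

import numpy as np
import pytest
from scipy import sparse

from sensopt.env_sim import make_maze
from sensopt.macrostates import MacrostateConfig, macro_transitions
from sensopt.microstates import TransitionModel, build_grid
from sensopt.navigation import (
    ControlConfigParams,
    control_config,
    grid_adjacency,
    plan,
    run_navigation_experiment,
    sample_goal_region,
    simulate_occupancy,
)

from conftest import corridor_model


@pytest.fixture(scope="module")
def grid20():
    return build_grid(make_maze("square", 20.0), 1.0)


class TestControlConfig:
    def test_single_gaussian_is_global_state(self, grid20, rng):
        cfg = control_config(grid20, ControlConfigParams(n_states=1), rng)
        assert cfg.n_macro == 1

    def test_two_equal_gaussians_bisect(self, grid20):
        # equal widths, left/right centers: the boundary is the
        # perpendicular bisector, here the vertical midline
        import sensopt.navigation as nav

        d2 = ((grid20.centers[:, None, :] - np.array([[-5.0, 0.0], [5.0, 0.0]])[None]) ** 2).sum(axis=2)
        labels = np.argmax(np.exp(-d2 / (2 * 2.0**2)), axis=1)
        left = grid20.centers[labels == 0]
        right = grid20.centers[labels == 1]
        assert left[:, 0].max() < 0 < right[:, 0].min()

    def test_requested_count_always_nonempty(self, grid20, rng):
        for n in (10, 50, 120):
            cfg = control_config(grid20, ControlConfigParams(n_states=n), rng)
            assert cfg.n_macro == n
            assert (cfg.sizes() > 0).all()

    def test_states_mostly_simply_connected(self, rng):
        # needs the canonical fine resolution: on coarse lattices the
        # winner-take-all boundaries pixelate into stray fragments
        from scipy import ndimage

        grid = build_grid(make_maze("square", 20.0), 1 / 3)
        frac_connected = []
        for _ in range(5):
            cfg = control_config(grid, ControlConfigParams(n_states=50), rng)
            img = grid.label_image(cfg.labels, fill=-1)
            ncomp = np.array(
                [ndimage.label(img == s, structure=np.ones((3, 3)))[1] for s in range(50)]
            )
            frac_connected.append((ncomp == 1).mean())
        assert np.mean(frac_connected) >= 0.9


class TestPlan:
    def test_deterministic_chain_policy(self, corridor5):
        # corridor: action 0 moves east; goal at the east end
        cfg = MacrostateConfig(labels=np.arange(5))
        TM = macro_transitions(cfg, corridor5)
        policy = plan(TM, [4])
        assert list(policy.action_of[:4]) == [0, 0, 0, 0]
        assert policy.reachable.all()

    def test_goal_state_has_defined_action(self, corridor5):
        cfg = MacrostateConfig(labels=np.arange(5))
        TM = macro_transitions(cfg, corridor5)
        policy = plan(TM, [2])
        assert 0 <= policy.action_of[2] < corridor5.n_actions

    def test_goal_flux_action_targets_goal_cells(self, corridor5):
        # one macrostate covering cells {3,4}; goal region is cell 4:
        # the flux-maximizing action is east (0), not west
        cfg = MacrostateConfig(labels=np.array([0, 1, 2, 3, 3]))
        TM = macro_transitions(cfg, corridor5)
        policy = plan(TM, [3], model=corridor5, config=cfg, goal_cells=np.array([4]))
        assert policy.action_of[3] == 0

    def test_unreachable_states_flagged(self):
        # two disconnected 2-cell islands
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 1.0
        dense[2, 3] = dense[3, 2] = 1.0
        model = TransitionModel(
            tm=[sparse.csr_matrix(dense)], visit_counts=np.full((4, 1), 5)
        )
        cfg = MacrostateConfig(labels=np.arange(4))
        TM = macro_transitions(cfg, model)
        policy = plan(TM, [0])
        assert policy.reachable[0] and policy.reachable[1]
        assert not policy.reachable[2] and not policy.reachable[3]


class TestSimulateOccupancy:
    def test_deterministic_corridor_three_steps(self, corridor5):
        cfg = MacrostateConfig(labels=np.arange(5))
        TM = macro_transitions(cfg, corridor5)
        policy = plan(TM, [4])
        res = simulate_occupancy(corridor5, cfg, policy, 1, np.array([4]), 0.95)
        assert res.steps_to_criterion == 3
        np.testing.assert_allclose(res.entropy_series[:3], 0.0, atol=1e-12)

    def test_start_inside_goal_rejected(self, corridor5):
        cfg = MacrostateConfig(labels=np.arange(5))
        TM = macro_transitions(cfg, corridor5)
        policy = plan(TM, [4])
        with pytest.raises(ValueError):
            simulate_occupancy(corridor5, cfg, policy, 4, np.array([4]), 0.95)

    def test_goal_probability_nondecreasing_and_mass_conserved(self, rng):
        # noisy 1-D model: occupancy is absorbed monotonically
        n = 12
        dense = np.zeros((n, n))
        for i in range(n):
            dense[i, min(i + 1, n - 1)] += 0.7
            dense[i, i] += 0.2
            dense[i, max(i - 1, 0)] += 0.1
        dense /= dense.sum(axis=1, keepdims=True)
        model = TransitionModel(
            tm=[sparse.csr_matrix(dense)], visit_counts=np.full((n, 1), 5)
        )
        cfg = MacrostateConfig(labels=np.arange(n))
        TM = macro_transitions(cfg, model)
        policy = plan(TM, [n - 1])
        res = simulate_occupancy(model, cfg, policy, 0, np.array([n - 1]), 0.95)
        assert res.reached
        assert (np.diff(res.goal_prob_series) >= -1e-12).all()

    def test_matches_dense_matrix_power_oracle(self, rng):
        # brute-force linear algebra: absorbed mass after t steps
        n = 6
        dense = rng.random((n, n)) + 0.1
        dense /= dense.sum(axis=1, keepdims=True)
        model = TransitionModel(
            tm=[sparse.csr_matrix(dense)], visit_counts=np.full((n, 1), 5)
        )
        cfg = MacrostateConfig(labels=np.arange(n))
        TM = macro_transitions(cfg, model)
        goal = np.array([n - 1])
        policy = plan(TM, [n - 1])
        res = simulate_occupancy(model, cfg, policy, 0, goal, 0.999, max_steps=20)
        # oracle: substochastic propagation with the goal row zeroed
        P = dense.copy()
        P[n - 1, :] = 0.0
        act = np.zeros(n)
        act[0] = 1.0
        absorbed = []
        tot = 0.0
        for _ in range(len(res.goal_prob_series)):
            act = act @ P
            tot += act[n - 1]
            act[n - 1] = 0.0
            absorbed.append(tot)
        np.testing.assert_allclose(res.goal_prob_series, absorbed, atol=1e-12)

    def test_uniform_occupancy_entropy(self):
        # n states with mass spread uniformly: entropy ln(n)
        n = 4
        dense = np.full((n, n), 1.0 / n)
        model = TransitionModel(
            tm=[sparse.csr_matrix(dense)], visit_counts=np.full((n, 1), 5)
        )
        cfg = MacrostateConfig(labels=np.arange(n))
        TM = macro_transitions(cfg, model)
        policy = plan(TM, [0])
        policy.action_of[:] = 0
        res = simulate_occupancy(model, cfg, policy, 1, np.array([]), 0.95, max_steps=3, min_steps=3)
        # with no goal cells nothing absorbs; occupancy is uniform
        np.testing.assert_allclose(res.entropy_series, np.log(n), atol=1e-9)


class TestGoalRegions:
    def test_connected_and_right_size(self, grid20, rng):
        adj = grid_adjacency(grid20)
        from scipy.sparse import csgraph

        for size in (1, 5, 20):
            goal = sample_goal_region(grid20, size, rng, adjacency=adj)
            assert len(goal) == size
            sub = adj[goal][:, goal]
            ncomp, _ = csgraph.connected_components(sub, directed=False)
            assert ncomp == 1


class TestExperiment:
    def test_identical_maps_give_unit_ratio(self, grid20, rng):
        # evaluating the same map in both arms: same steps, ratio 1
        import pandas as pd

        from sensopt import navigation as nav

        maze = make_maze("square", 20.0)
        from sensopt.env_sim import MotorParams
        from sensopt.microstates import explore, restrict_to_sampled

        model = explore(
            maze, MotorParams(step_length=1.0), grid20,
            min_visits=30, coverage=0.9, rng=rng,
        )
        model, grid = restrict_to_sampled(model, grid20)
        cfg = control_config(grid, ControlConfigParams(n_states=30), rng)
        TM = macro_transitions(cfg, model)
        adj = nav.grid_adjacency(grid)
        goal = nav.sample_goal_region(grid, 10, rng, adjacency=adj)
        start = int(np.setdiff1d(np.arange(grid.n_cells), goal)[0])
        r1 = nav.evaluate_map(model, cfg, TM, start, goal)
        r2 = nav.evaluate_map(model, cfg, TM, start, goal)
        assert r1.steps_to_criterion == r2.steps_to_criterion
        np.testing.assert_allclose(r1.entropy_series, r2.entropy_series)

    def test_paired_trials_table(self, grid20, rng):
        from sensopt.env_sim import MotorParams
        from sensopt.microstates import explore, restrict_to_sampled

        maze = make_maze("square", 20.0)
        model = explore(
            maze, MotorParams(step_length=1.0), grid20,
            min_visits=30, coverage=0.9, rng=rng,
        )
        model, grid = restrict_to_sampled(model, grid20)
        cfg = control_config(grid, ControlConfigParams(n_states=25), rng)
        table = run_navigation_experiment(model, grid, cfg, rng, n_trials=5)
        assert len(table) == 5
        assert {"steps_optimized", "steps_control", "entropy_ratio"} <= set(table.columns)
        reached = table[table.reached_optimized]
        assert (reached.steps_optimized > 0).all()
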