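"""Unit and property tests of the lattice clonal-competition simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clonaldrift.lattice import (
    BoundaryError,
    LatticeState,
    SimConfig,
    _thirds_bounds,
    clone_stats_by_region,
    divide_cell,
    ensemble_summary,
    init_grid,
    render_color_grid,
    replicate_rngs,
    run_simulation,
    step_cycle,
)


def state_from_rows(*rows_bottom_to_top):
    """Build a LatticeState from bottom-to-top row lists."""
    return LatticeState(grid=np.array(rows_bottom_to_top, dtype=np.int32))


class TestInitGrid:
    @pytest.mark.parametrize("w,h", [(60, 60), (2, 2), (1, 2), (5, 3)])
    def test_each_identifier_appears_exactly_once(self, w, h):
        cfg = SimConfig(width=w, height=h, seed=42)
        state = init_grid(cfg)
        assert state.cycle == 0
        assert state.grid.shape == (h, w)
        assert np.array_equal(np.sort(state.grid, axis=None), np.arange(1, w * h + 1))
        assert state.clone_count == w * h
        assert float(state.clone_sizes().mean()) == 1.0

    @pytest.mark.parametrize("kwargs", [{"width": 0}, {"height": 1}, {"height": 0}])
    def test_degenerate_dimensions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestDivideCell:
    def test_upward_division_shifts_column_and_discards_top(self):
        # single column bottom->top [a, b, c]; dividing a upward gives [a, a, b]
        state = state_from_rows([1], [2], [3])
        new = divide_cell(state, col=0, row=0, direction="up")
        assert new.grid[:, 0].tolist() == [1, 1, 2]
        assert state.grid[:, 0].tolist() == [1, 2, 3]  # input untouched

    def test_lateral_division_shifts_target_column_up(self):
        # bottom [a, b], top [c, d]; a divides rightward -> bottom [a, a], top [c, b]
        state = state_from_rows([1, 2], [3, 4])
        new = divide_cell(state, col=0, row=0, direction="right")
        assert new.grid[0].tolist() == [1, 1]
        assert new.grid[1].tolist() == [3, 2]

    def test_top_row_upward_division_discards_the_copy(self):
        state = state_from_rows([1, 2], [3, 4])
        new = divide_cell(state, col=0, row=1, direction="up")
        assert np.array_equal(new.grid, state.grid)

    def test_lateral_at_wall_raises_under_reflecting_boundary(self):
        state = state_from_rows([1, 2], [3, 4])
        with pytest.raises(BoundaryError):
            divide_cell(state, col=0, row=0, direction="left")

    def test_lateral_at_wall_wraps_under_periodic_boundary(self):
        state = state_from_rows([1, 2], [3, 4])
        new = divide_cell(state, col=0, row=0, direction="left", boundary="periodic")
        assert new.grid[0].tolist() == [1, 1]
        assert new.grid[1].tolist() == [3, 2]

    def test_division_conserves_cell_count(self):
        state = state_from_rows([1, 2], [3, 4])
        for direction in ("up", "right"):
            assert divide_cell(state, 0, 0, direction).grid.size == 4


class TestStepCycle:
    @pytest.mark.parametrize("p_central", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_column_of_two_is_monoclonal_after_one_cycle(self, p_central, seed):
        # with no lateral neighbors the edge cell must divide upward
        cfg = SimConfig(width=1, height=2, p_central=p_central, seed=seed)
        rng = np.random.default_rng(seed)
        state = step_cycle(init_grid(cfg, rng), cfg, rng)
        assert state.clone_count == 1

    def test_monoclonal_after_exactly_height_minus_one_cycles(self):
        # p_central = 0: the edge identifier advances exactly one row per cycle
        cfg = SimConfig(width=1, height=10, p_central=0.0, seed=0)
        rng = np.random.default_rng(0)
        state = init_grid(cfg, rng)
        for _ in range(8):
            state = step_cycle(state, cfg, rng)
        assert state.clone_count == 2
        state = step_cycle(state, cfg, rng)
        assert state.clone_count == 1

    def test_two_by_two_yields_two_or_three_clones(self):
        cfg = SimConfig(width=2, height=2, p_central=0.0, seed=0)
        rng = np.random.default_rng(7)
        observed = set()
        for _ in range(500):
            observed.add(step_cycle(init_grid(cfg, rng), cfg, rng).clone_count)
        assert observed == {2, 3}

    def test_one_default_cycle_loses_some_but_not_all_clones(self):
        cfg = SimConfig(seed=11)
        rng = np.random.default_rng(11)
        state = step_cycle(init_grid(cfg, rng), cfg, rng)
        assert 0 < state.clone_count < 3600
        assert state.cycle == 1

    @given(
        w=st.integers(1, 6),
        h=st.integers(2, 6),
        seed=st.integers(0, 1000),
        variant=st.sampled_from(["probabilistic", "every_nth_row"]),
    )
    def test_invariants_conservation_monotonicity_subset(self, w, h, seed, variant):
        cfg = SimConfig(width=w, height=h, p_central=0.5, seed=seed, central_variant=variant)
        rng = np.random.default_rng(seed)
        state = init_grid(cfg, rng)
        prev_ids = set(np.unique(state.grid))
        for _ in range(5):
            state = step_cycle(state, cfg, rng)
            ids = set(np.unique(state.grid))
            assert state.grid.size == w * h  # conservation
            assert ids <= prev_ids  # identifiers only disappear
            assert len(ids) <= len(prev_ids)  # monotone clone count
            prev_ids = ids


class TestRunSimulation:
    def test_single_column_trajectory_reaches_monoclonality(self):
        cfg = SimConfig(width=1, height=10, cycles=9, p_central=0.0, seed=0)
        traj = run_simulation(cfg)
        assert traj.final_state.clone_count == 1

    def test_zero_cycles_trajectory_is_the_initial_record(self):
        cfg = SimConfig(cycles=0, seed=0)
        traj = run_simulation(cfg)
        assert len(traj.records) == 1
        assert traj.records[0]["clones_total"] == 3600
        assert traj.records[0]["mean_clone_size"] == 1.0

    def test_mean_size_grows_and_clone_count_falls(self):
        # expectation over seeded runs at reduced scale
        growing, falling = 0, 0
        for seed in range(20):
            cfg = SimConfig(width=20, height=20, cycles=10, seed=seed)
            df = run_simulation(cfg).to_frame()
            growing += df.mean_clone_size.iloc[-1] > df.mean_clone_size.iloc[0]
            falling += df.clones_total.iloc[-1] < df.clones_total.iloc[0]
        assert growing == 20
        assert falling == 20

    def test_detached_clones_rarely_survive(self):
        # clones without edge contact drift into necrosis; after 3*H cycles
        # almost every survivor retains a bottom-row cell
        detached = total = 0
        cfg = SimConfig(width=20, height=20, cycles=0)
        for rng in replicate_rngs(99, 20):
            state = init_grid(cfg, rng)
            for _ in range(60):
                state = step_cycle(state, cfg, rng)
            survivors = set(np.unique(state.grid))
            edge_ids = set(np.unique(state.grid[0]))
            detached += len(survivors - edge_ids)
            total += len(survivors)
        assert detached / total < 0.05


class TestRegionsAndRendering:
    def test_fresh_grid_counts_every_identifier_per_third(self):
        stats = clone_stats_by_region(init_grid(SimConfig(seed=0)))
        assert stats["clones_total"] == 3600
        assert stats["clones_edge_third"] == 1200
        assert stats["clones_mid_third"] == 1200
        assert stats["clones_center_third"] == 1200

    def test_monoclonal_grid_counts_one_everywhere(self):
        state = LatticeState(grid=np.full((6, 4), 7, dtype=np.int32))
        stats = clone_stats_by_region(state)
        assert stats["clones_total"] == 1
        assert (
            stats["clones_edge_third"]
            == stats["clones_mid_third"]
            == stats["clones_center_third"]
            == 1
        )

    def test_column_clone_spanning_all_thirds_counts_in_each(self):
        grid = np.full((6, 4), 2, dtype=np.int32)
        grid[:, 0] = 1
        stats = clone_stats_by_region(LatticeState(grid=grid))
        assert stats["clones_edge_third"] == 2
        assert stats["clones_center_third"] == 2

    def test_uneven_height_assigns_extra_rows_to_middle_third(self):
        assert _thirds_bounds(7) == (2, 5)  # edge 2 rows, middle 3, center 2
        assert _thirds_bounds(60) == (20, 40)

    @pytest.mark.parametrize("ident,color", [(13, 3), (10, 0), (3600, 0), (1, 1)])
    def test_color_is_identifier_modulo_palette(self, ident, color):
        state = LatticeState(grid=np.array([[ident]], dtype=np.int32))
        assert render_color_grid(state, palette_size=10)[0, 0] == color


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_trajectories(self):
        cfg = SimConfig(width=15, height=15, cycles=8, seed=77)
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert np.array_equal(a.final_state.grid, b.final_state.grid)
        assert a.to_frame().equals(b.to_frame())

    def test_identical_master_seed_reproduces_ensembles(self):
        cfg = SimConfig(width=10, height=10, cycles=5, replicates=4, seed=3)
        a, b = ensemble_summary(cfg), ensemble_summary(cfg)
        assert a.per_replicate.equals(b.per_replicate)

    def test_ensemble_of_one_is_the_single_subseeded_trajectory(self):
        cfg = SimConfig(width=10, height=10, cycles=5, replicates=1, seed=3)
        ens = ensemble_summary(cfg)
        solo = run_simulation(cfg, rng=replicate_rngs(cfg.seed, 1)[0]).to_frame()
        assert ens.per_replicate.drop(columns="replicate").equals(solo)
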