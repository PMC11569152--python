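"""Competitive allocation: probabilities, convergence, conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from deltaclue.allocation import (
    AllocationParams,
    AllocationState,
    InfeasibleAllocationError,
    NonConvergenceError,
    allocate_year,
    cell_probability,
    run_simulation,
)
from deltaclue.grid import GridSpec
from deltaclue.suitability import fit_all_classes

from conftest import raster_from


def uniform_suit(spec, codes, value=0.5):
    return {c: np.full(spec.shape, value) for c in codes}


class TestCellProbability:
    def test_staying_bonus(self):
        stay = cell_probability(0.0, 0.9, 0.0, 0.0, is_current=True)
        move = cell_probability(0.0, 0.9, 0.0, 0.0, is_current=False)
        assert stay == 0.9 and move == 0.0

    def test_additive_composition(self):
        p = cell_probability(0.3, 0.1, 0.5, -0.2, locspec_weight=2.0, is_current=True)
        assert p == pytest.approx(0.3 + 2.0 * 0.5 - 0.2 + 0.1)

    def test_zero_elasticity_reduces_to_suitability_ranking(self, spec2):
        codes = [0, 1]
        lu = raster_from(spec2, [[0, 0], [1, 1]])
        suit = {0: np.array([[0.9, 0.1], [0.8, 0.2]]),
                1: np.array([[0.1, 0.9], [0.2, 0.8]])}
        demand = pd.Series({0: 200.0, 1: 200.0})
        state = AllocationState.initial(lu)
        allow = pd.DataFrame(1, index=codes, columns=codes)
        new, _ = allocate_year(state, demand, suit, {0: 0.0, 1: 0.0}, allow)
        np.testing.assert_array_equal(new.landuse.values, [[0, 1], [0, 1]])


class TestAllocateYear:
    def test_identity_when_demand_matches_and_elas_one(self, spec2):
        codes = [0, 1]
        lu = raster_from(spec2, [[0, 0], [1, 1]])
        demand = pd.Series({0: 200.0, 1: 200.0})
        state = AllocationState.initial(lu)
        allow = pd.DataFrame(1, index=codes, columns=codes)
        new, log = allocate_year(state, demand, uniform_suit(spec2, codes),
                                 {0: 1.0, 1: 1.0}, allow)
        np.testing.assert_array_equal(new.landuse.values, lu.values)
        assert log["iterations"] == 1

    def test_four_cell_toy_matches_brute_force(self):
        # 4 cells currently A(0); demand 2 A + 2 B(1); elasticity 0; the
        # optimal assignment maximises total probability subject to the
        # demand constraint -> enumerated over all C(4,2)=6 options
        spec = GridSpec(ncols=4, nrows=1, cellsize=1000.0)
        suit_b = np.array([[0.9, 0.6, 0.4, 0.1]])
        suit_a = 1.0 - suit_b
        best, best_total = None, -np.inf
        for combo in itertools.combinations(range(4), 2):
            total = sum(suit_b[0, i] if i in combo else suit_a[0, i] for i in range(4))
            if total > best_total:
                best, best_total = combo, total
        assert best == (0, 1)

        lu = raster_from(spec, [[0, 0, 0, 0]])
        demand = pd.Series({0: 200.0, 1: 200.0})
        allow = pd.DataFrame(1, index=[0, 1], columns=[0, 1])
        new, _ = allocate_year(
            AllocationState.initial(lu), demand, {0: suit_a, 1: suit_b},
            {0: 0.0, 1: 0.0}, allow,
            params=AllocationParams(tolerance=0.004, step_gain=0.02),
        )
        np.testing.assert_array_equal(new.landuse.values, [[1, 1, 0, 0]])

    def test_elasticity_one_class_cannot_shrink(self):
        # all 10 cells are A with elasticity 1.0; demand requires A -> B
        spec = GridSpec(ncols=10, nrows=1, cellsize=1000.0)
        lu = raster_from(spec, [[0] * 10])
        demand = pd.Series({0: 500.0, 1: 500.0})
        allow = pd.DataFrame(1, index=[0, 1], columns=[0, 1])
        with pytest.raises(NonConvergenceError) as err:
            allocate_year(
                AllocationState.initial(lu), demand, uniform_suit(spec, [0, 1]),
                {0: 1.0, 1: 0.0}, allow,
                params=AllocationParams(max_iterations=50),
            )
        # both classes sit at 100% deviation: A never yields its 10 cells
        assert err.value.deviations.max() == pytest.approx(1.0)

    def test_disallowed_demand_is_infeasible(self):
        spec = GridSpec(ncols=4, nrows=1, cellsize=1000.0)
        lu = raster_from(spec, [[0, 0, 0, 0]])
        demand = pd.Series({0: 200.0, 1: 200.0})
        allow = pd.DataFrame(np.eye(2, dtype=int), index=[0, 1], columns=[0, 1])
        with pytest.raises(InfeasibleAllocationError):
            allocate_year(AllocationState.initial(lu), demand,
                          uniform_suit(spec, [0, 1]), {0: 0.0, 1: 0.0}, allow)

    def test_restricted_cells_never_change(self, spec2):
        codes = [0, 1]
        lu = raster_from(spec2, [[0, 0], [1, 1]])
        restricted = np.array([[True, False], [False, False]])
        # demand forces class 0 down to one cell; the restricted 0-cell must survive
        demand = pd.Series({0: 100.0, 1: 300.0})
        allow = pd.DataFrame(1, index=codes, columns=codes)
        suit = {0: np.array([[0.9, 0.8], [0.1, 0.1]]),
                1: np.array([[0.1, 0.2], [0.9, 0.9]])}
        new, _ = allocate_year(
            AllocationState.initial(lu, restricted=restricted), demand, suit,
            {0: 0.0, 1: 0.0}, allow,
        )
        assert new.landuse.values[0, 0] == 0
        assert (new.landuse.values[restricted] == lu.values[restricted]).all()

    def test_age_resets_on_change(self, spec2):
        codes = [0, 1]
        lu = raster_from(spec2, [[0, 0], [1, 1]])
        demand = pd.Series({0: 100.0, 1: 300.0})
        allow = pd.DataFrame(1, index=codes, columns=codes)
        suit = {0: np.array([[0.9, 0.1], [0.1, 0.1]]),
                1: np.array([[0.1, 0.9], [0.9, 0.9]])}
        state = AllocationState.initial(lu)
        state.age += 5
        new, _ = allocate_year(state, demand, suit, {0: 0.0, 1: 0.0}, allow)
        changed = new.landuse.values != lu.values
        assert (new.age[changed] == 0).all()
        assert (new.age[~changed & new.landuse.data_mask] == 6).all()

    def test_competition_shift_is_monotone(self, world):
        """Raising one class's competition never shrinks its argmax share."""
        codes = world.landuse0.class_codes()
        suit = {c: np.full(world.spec.shape, 0.5) for c in codes}
        rng = np.random.default_rng(0)
        for c in codes:
            suit[c] += 0.1 * rng.standard_normal(world.spec.shape)
        counts = []
        for delta in (0.0, 0.05, 0.1, 0.2):
            p = np.stack([suit[c] + (delta if c == 0 else 0.0) for c in codes])
            counts.append(int((np.argmax(p, axis=0) == 0).sum()))
        assert counts == sorted(counts)


@pytest.fixture(scope="module")
def sim_inputs(world):
    models = fit_all_classes(world.landuse0, world.drivers)
    codes = world.landuse0.class_codes()
    counts = pd.Series(world.landuse0.class_counts(codes), dtype=float)
    return world, models, codes, counts * 100.0


class TestRunSimulation:
    def test_constant_demand_is_stationary_after_year_one(self, sim_inputs):
        world, models, codes, areas = sim_inputs
        traj = pd.DataFrame([areas] * 3, index=[1, 2, 3])
        allow = pd.DataFrame(1, index=codes, columns=codes)
        maps, log = run_simulation(
            world.landuse0, [1, 2, 3], traj, lambda y: world.drivers, models,
            {c: 1.0 for c in codes}, allow,
        )
        for y in (1, 2, 3):
            np.testing.assert_array_equal(maps[y].values, world.landuse0.values)

    def test_demand_shift_met_within_tolerance(self, sim_inputs):
        world, models, codes, areas = sim_inputs
        end = areas.copy()
        shift = round(0.10 * areas.sum() / 100) * 100
        end[codes[0]] -= shift
        end[codes[-1]] += shift
        years = list(range(1, 6))
        traj = pd.DataFrame(
            [areas + (end - areas) * t / 5 for t in years], index=years
        )
        allow = pd.DataFrame(1, index=codes, columns=codes)
        params = AllocationParams()
        maps, log = run_simulation(
            world.landuse0, years, traj, lambda y: world.drivers, models,
            {c: 0.2 for c in codes}, allow, params=params,
        )
        assert (log["max_deviation"] <= params.tolerance).all()
        final = pd.Series(maps[5].class_counts(codes), dtype=float) * 100.0
        rel = (final - traj.loc[5]).abs() / traj.loc[5]
        assert (rel <= params.tolerance + 1e-12).all()

    def test_total_active_area_conserved(self, sim_inputs):
        world, models, codes, areas = sim_inputs
        traj = pd.DataFrame([areas] * 2, index=[1, 2])
        allow = pd.DataFrame(1, index=codes, columns=codes)
        maps, _ = run_simulation(
            world.landuse0, [1, 2], traj, lambda y: world.drivers, models,
            {c: 0.5 for c in codes}, allow,
        )
        for m in maps.values():
            assert int(m.data_mask.sum()) == int(world.landuse0.data_mask.sum())

    def test_deterministic_given_inputs(self, sim_inputs):
        world, models, codes, areas = sim_inputs
        traj = pd.DataFrame([areas] * 2, index=[1, 2])
        allow = pd.DataFrame(1, index=codes, columns=codes)
        run = lambda: run_simulation(
            world.landuse0, [1, 2], traj, lambda y: world.drivers, models,
            {c: 0.3 for c in codes}, allow,
        )[0]
        a, b = run(), run()
        for y in (1, 2):
            np.testing.assert_array_equal(a[y].values, b[y].values)
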