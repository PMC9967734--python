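"""Markov estimation, suitability, scenario constraints and CA allocation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenrisk import lucc
from greenrisk.lucc import (ScenarioRules, apply_scenario_constraints,
                            build_suitability, estimate_transition, kappa,
                            project_class_areas, simulate_ca)
from greenrisk.raster import (CONSTRUCTION, CULTIVATED, FOREST, GRASSLAND,
                              Raster, CLASS_CODES)
from greenrisk.synthetic import DriverStack

from conftest import make_raster


class TestEstimateTransition:
    def test_identical_maps_give_identity(self, small_landscape):
        base, _ = small_landscape
        model = estimate_transition(base, base)
        np.testing.assert_allclose(model.prob_matrix, np.eye(6), atol=1e-12)

    def test_two_by_two_hand_count(self):
        t0 = make_raster([[1, 1], [2, 2]])
        t1 = make_raster([[1, 2], [2, 2]])
        model = estimate_transition(t0, t1)
        assert model.area_matrix[0, 0] == 1
        assert model.area_matrix[0, 1] == 1
        assert model.area_matrix[1, 1] == 2
        np.testing.assert_allclose(model.prob_matrix[0],
                                   [0.5, 0.5, 0, 0, 0, 0])

    def test_absent_class_becomes_identity_row(self):
        t0 = make_raster([[1, 1], [1, 1]])
        model = estimate_transition(t0, t0)
        np.testing.assert_allclose(model.prob_matrix[3],
                                   np.eye(6)[3])

    def test_area_rows_sum_to_source_counts(self, small_landscape):
        base, epoch2 = small_landscape
        model = estimate_transition(base, epoch2)
        np.testing.assert_array_equal(model.area_matrix.sum(axis=1),
                                      base.class_counts())

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            estimate_transition(make_raster(np.ones((2, 2), int)),
                                make_raster(np.ones((3, 3), int)))

    def test_all_nodata_raises(self):
        z = make_raster(np.zeros((4, 4), int))
        with pytest.raises(ValueError):
            estimate_transition(z, z)


class TestProjectAreas:
    def test_identity_keeps_counts(self, small_landscape):
        base, _ = small_landscape
        model = estimate_transition(base, base)
        np.testing.assert_array_equal(
            project_class_areas(model, base, steps=3), base.class_counts())

    def test_forest_to_cultivated_demand(self):
        t0 = make_raster([[1, 1, 2], [2, 2, 1]])
        P = np.eye(6)
        P[1] = 0
        P[1, 0] = 1.0
        model = lucc.TransitionModel(P, np.zeros((6, 6), int))
        targets = project_class_areas(model, t0, steps=1)
        assert targets[0] == 6 and targets[1] == 0

    def test_uniform_matrix_equal_targets(self):
        t0 = make_raster(np.ones((60, 60), int))
        model = lucc.TransitionModel(np.full((6, 6), 1 / 6),
                                     np.zeros((6, 6), int))
        np.testing.assert_array_equal(
            project_class_areas(model, t0, steps=1), [600] * 6)

    def test_matches_naive_markov_loop(self, small_landscape):
        """Matrix-power demand equals repeated naive vector multiplication."""
        base, epoch2 = small_landscape
        model = estimate_transition(base, epoch2)
        counts = base.class_counts().astype(float)
        expected = counts.copy()
        for _ in range(4):
            expected = np.array(
                [sum(expected[i] * model.prob_matrix[i, j]
                     for i in range(6)) for j in range(6)])
        got = project_class_areas(model, base, steps=4)
        assert np.abs(got - expected).max() < 1.0 + 1e-9
        assert got.sum() == base.n_valid()


class TestLargestRemainder:
    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1000), min_size=6, max_size=6),
           st.integers(0, 100000))
    def test_rounded_demands_conserve_total(self, weights, total):
        """Fractional Markov demands round to integers summing exactly."""
        w = np.asarray(weights) + 1e-9
        fractions = w / w.sum() * total
        rounded = lucc._largest_remainder(fractions, total)
        assert rounded.sum() == total
        assert (rounded >= 0).all()
        assert np.abs(rounded - fractions).max() <= 1.0 + 1e-6


class TestSuitability:
    def _stack(self, layers):
        return DriverStack(layers={k: make_raster(v, nodata=-1)
                                   for k, v in layers.items()})

    def test_constant_driver_constant_suitability(self):
        stack = self._stack({n: np.full((5, 5), 3.0)
                             for n in lucc.DEFAULT_ORIENTATIONS[1]})
        atlas = build_suitability(stack, ScenarioRules("NP"))
        for cls in CLASS_CODES:
            assert np.allclose(atlas.suitability[cls].values, 0.5)

    def test_zero_constraint_zeroes_suitability(self):
        shape = (5, 5)
        stack = self._stack({n: np.random.default_rng(0).random(shape)
                             for n in lucc.DEFAULT_ORIENTATIONS[1]})
        constraints = {c: np.ones(shape, dtype=bool) for c in CLASS_CODES}
        constraints[3] = np.zeros(shape, dtype=bool)
        atlas = build_suitability(stack, ScenarioRules("NP"),
                                  constraints=constraints)
        assert (atlas.suitability[3].values == 0).all()

    def test_weighted_mean_of_two_drivers(self):
        vals_a = np.zeros((4, 4))
        vals_a[0, 0] = 1.0          # rescales to itself
        vals_a[1, 1] = 0.2
        vals_b = np.zeros((4, 4))
        vals_b[0, 0] = 1.0
        vals_b[1, 1] = 0.8
        stack = self._stack({"elevation": vals_a, "slope": vals_b})
        weights = {c: {"elevation": 0.5, "slope": 0.5} for c in CLASS_CODES}
        orient = {c: {"elevation": +1, "slope": +1} for c in CLASS_CODES}
        atlas = build_suitability(stack, ScenarioRules("NP"),
                                  weights=weights, orientations=orient)
        assert atlas.suitability[1].values[1, 1] == pytest.approx(0.5)

    def test_missing_driver_raises(self):
        stack = self._stack({"elevation": np.ones((3, 3))})
        with pytest.raises(KeyError):
            build_suitability(stack, ScenarioRules("NP"))

    def test_bad_weight_sum_raises(self):
        stack = self._stack({"elevation": np.ones((3, 3))})
        weights = {c: {"elevation": 0.7} for c in CLASS_CODES}
        with pytest.raises(ValueError):
            build_suitability(stack, ScenarioRules("NP"), weights=weights)


class TestScenarioConstraints:
    def _fixture(self):
        lu = make_raster([[1, 1, 2], [2, 5, 6], [1, 4, 3]])
        slope = np.array([[20., 5, 5], [5, 5, 5], [10, 5, 5]])
        blacksoil = np.array([[0, 0, 1], [0, 0, 0], [0, 0, 0]], dtype=int)
        stack = DriverStack(
            layers={"slope": make_raster(slope, nodata=-1)},
            blacksoil=make_raster(blacksoil, nodata=-1))
        return lu, stack

    def test_np_scenario_all_permissive(self):
        lu, stack = self._fixture()
        masks = apply_scenario_constraints(ScenarioRules("NP"), stack, lu)
        assert all(m.all() for m in masks.values())

    def test_steep_cultivated_only_forest_or_grass(self):
        lu, stack = self._fixture()
        masks = apply_scenario_constraints(ScenarioRules("BCU"), stack, lu)
        # cell (0,0): cultivated, slope 20 deg
        allowed = {c for c in CLASS_CODES if masks[c][0, 0] and c != 1}
        assert allowed == {FOREST, GRASSLAND}

    def test_flat_cultivated_fully_frozen(self):
        lu, stack = self._fixture()
        masks = apply_scenario_constraints(ScenarioRules("BCU"), stack, lu)
        # cell (0,1): cultivated, slope 5 deg -- no outbound conversion
        assert not any(masks[c][0, 1] for c in CLASS_CODES if c != 1)

    def test_blacksoil_blocks_construction(self):
        lu, stack = self._fixture()
        masks = apply_scenario_constraints(ScenarioRules("BCU"), stack, lu)
        assert not masks[CONSTRUCTION][0, 2]      # forest on blacksoil

    def test_steep_cells_not_reclaimed(self):
        lu, stack = self._fixture()
        masks = apply_scenario_constraints(ScenarioRules("BCU"), stack, lu)
        assert not masks[CULTIVATED][0, 0]

    def test_green_protected_from_construction(self):
        lu, stack = self._fixture()
        masks = apply_scenario_constraints(ScenarioRules("BCU"), stack, lu)
        green = np.isin(lu.values, (1, 2, 3, 4))
        assert not masks[CONSTRUCTION][green].any()

    def test_bcu_without_slope_raises(self):
        lu, _ = self._fixture()
        with pytest.raises(ValueError):
            apply_scenario_constraints(ScenarioRules("BCU"),
                                       DriverStack(layers={}), lu)


def _np_atlas(drivers, map_t0):
    rules = ScenarioRules("NP")
    return build_suitability(
        drivers, rules,
        constraints=apply_scenario_constraints(rules, drivers, map_t0))


class TestSimulateCA:
    def test_zero_demand_is_identity(self, small_landscape, small_config,
                                     desk_drivers):
        base, _ = small_landscape
        from greenrisk.synthetic import generate_drivers
        drivers = generate_drivers(small_config, base)
        atlas = _np_atlas(drivers, base)
        out = simulate_ca(base, base.class_counts(), atlas, seed=4)
        np.testing.assert_array_equal(out.values, base.values)

    def test_counts_hit_targets_within_one_percent(
            self, small_landscape, small_config):
        base, epoch2 = small_landscape
        from greenrisk.synthetic import generate_drivers
        drivers = generate_drivers(small_config, base)
        model = estimate_transition(base, epoch2)
        targets = project_class_areas(model, epoch2, steps=1)
        atlas = _np_atlas(drivers, epoch2)
        out = simulate_ca(epoch2, targets, atlas, seed=5)
        assert out.n_valid() == epoch2.n_valid()
        gap = np.abs(out.class_counts() - targets).max()
        assert gap <= 0.01 * epoch2.n_valid()

    def test_infeasible_targets_warn_not_violate(self, small_landscape,
                                                 small_config):
        base, _ = small_landscape
        from greenrisk.synthetic import generate_drivers
        drivers = generate_drivers(small_config, base)
        atlas = _np_atlas(drivers, base)
        # forbid all conversion to construction, then demand all construction
        atlas.constraints[5][:] = False
        targets = np.zeros(6, dtype=int)
        targets[4] = base.n_valid()
        with pytest.warns(RuntimeWarning, match="shortfall"):
            out = simulate_ca(base, targets, atlas, seed=6)
        grew = (out.values == 5) & (base.values != 5)
        assert not grew.any()

    def test_raising_suitability_keeps_cell_converted(
            self, small_landscape, small_config):
        """Allocation priority is monotone in suitability."""
        base, epoch2 = small_landscape
        from greenrisk.synthetic import generate_drivers
        drivers = generate_drivers(small_config, base)
        model = estimate_transition(base, epoch2)
        targets = project_class_areas(model, epoch2, steps=1)
        atlas = _np_atlas(drivers, epoch2)
        out = simulate_ca(epoch2, targets, atlas, seed=7)
        converted = (out.values == 1) & (epoch2.values != 1)
        assert converted.any()
        r, c = np.argwhere(converted)[0]
        atlas.suitability[1].values[r, c] = 1.0
        out2 = simulate_ca(epoch2, targets, atlas, seed=7)
        assert out2.values[r, c] == 1

    def test_bad_target_sum_raises(self, small_landscape, small_config):
        base, _ = small_landscape
        from greenrisk.synthetic import generate_drivers
        drivers = generate_drivers(small_config, base)
        atlas = _np_atlas(drivers, base)
        with pytest.raises(ValueError):
            simulate_ca(base, np.zeros(6, int), atlas)


class TestKappa:
    def test_identical_maps(self, small_landscape):
        base, _ = small_landscape
        assert kappa(base, base) == pytest.approx(1.0)

    def test_hand_confusion_matrix(self):
        # 2-class confusion (40,10;10,40): p_o=0.8, p_e=0.5, kappa=0.6
        a = np.array([1] * 50 + [2] * 50)
        b = np.array([1] * 40 + [2] * 10 + [1] * 10 + [2] * 40)
        assert kappa(make_raster(a.reshape(10, 10)),
                     make_raster(b.reshape(10, 10))) == pytest.approx(0.6)

    def test_perfect_disagreement(self):
        a = make_raster([[1, 2], [1, 2]])
        b = make_raster([[2, 1], [2, 1]])
        assert kappa(a, b) == pytest.approx(-1.0)

    def test_matches_sklearn(self, small_landscape):
        from sklearn.metrics import cohen_kappa_score
        base, epoch2 = small_landscape
        ours = kappa(base, epoch2)
        ref = cohen_kappa_score(base.values.ravel(), epoch2.values.ravel())
        assert ours == pytest.approx(ref, abs=1e-12)
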