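"""Desirability scoring, optimization and design-space mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanoform as nf
from nanoform.desirability import GoalError, desirability_at, feasible_at

MIN_SIZE = nf.Goal("particle_size", "minimize", 139.0, 210.0, weight=1.0, importance=1)
MAX_EE = nf.Goal("ee", "maximize", 58.7, 75.6, weight=1.0, importance=5)


class TestIndividualDesirability:
    @pytest.mark.parametrize(
        "goal, value, expected",
        [
            (MIN_SIZE, 210.0, 0.0),
            (MIN_SIZE, 139.0, 1.0),
            (MIN_SIZE, 250.0, 0.0),  # clamped beyond the upper limit
            (MAX_EE, 67.15, 0.5),  # linear midpoint
            (MAX_EE, 58.7, 0.0),
            (MAX_EE, 80.0, 1.0),
            (MIN_SIZE, 141.145, (210 - 141.145) / 71.0),
        ],
    )
    def test_boundary_and_midpoint_values(self, goal, value, expected):
        assert nf.individual_desirability(value, goal) == pytest.approx(expected, abs=5e-4)

    def test_in_range_is_indicator(self):
        goal = nf.Goal("PLGA", "in_range", 33.3, 100.0)
        assert nf.individual_desirability(50.0, goal) == 1.0
        assert nf.individual_desirability(120.0, goal) == 0.0

    def test_weight_curves_the_ramp(self):
        heavy = nf.Goal("particle_size", "minimize", 139.0, 210.0, weight=3.0)
        mid = (139.0 + 210.0) / 2
        assert nf.individual_desirability(mid, heavy) == pytest.approx(0.125)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(100, 250),
        st.floats(100, 250),
        st.floats(0.2, 5.0),
    )
    def test_minimize_monotone_and_bounded(self, v1, v2, weight):
        goal = nf.Goal("y", "minimize", 139.0, 210.0, weight=weight)
        d1, d2 = nf.individual_desirability(v1, goal), nf.individual_desirability(v2, goal)
        assert 0.0 <= d1 <= 1.0
        if v1 <= v2:
            assert d1 >= d2 - 1e-12

    @settings(max_examples=100, deadline=None)
    @given(st.floats(40, 90), st.floats(40, 90))
    def test_maximize_monotone(self, v1, v2):
        d1 = nf.individual_desirability(v1, MAX_EE)
        d2 = nf.individual_desirability(v2, MAX_EE)
        if v1 <= v2:
            assert d1 <= d2 + 1e-12

    def test_invalid_goals_rejected(self):
        with pytest.raises(GoalError):
            nf.Goal("y", "minimize", 210.0, 139.0)
        with pytest.raises(GoalError):
            nf.Goal("y", "minimize", 139.0, 210.0, weight=0.0)
        with pytest.raises(GoalError):
            nf.Goal("y", "minimize", 139.0, 210.0, importance=6)
        with pytest.raises(GoalError):
            nf.Goal("y", "target", 139.0, 210.0)


class TestOverallDesirability:
    def test_all_ones_give_one_and_any_zero_gives_zero(self):
        assert nf.overall_desirability([1.0, 1.0, 1.0], [1, 3, 5]) == 1.0
        assert nf.overall_desirability([1.0, 0.0, 0.9], [1, 3, 5]) == 0.0

    def test_importance_weighted_combination(self):
        # d = 0.9698 (r=1) with a saturated d = 1 (r=5): 0.9698^(1/6)
        assert nf.overall_desirability([0.9698, 1.0], [1, 5]) == pytest.approx(
            0.99491, abs=1e-4
        )

    def test_equal_importances_reduce_to_geometric_mean(self):
        d = np.array([0.3, 0.6, 0.9])
        expected = float(np.exp(np.log(d).mean()))
        assert nf.overall_desirability(d, [2, 2, 2]) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
        st.data(),
    )
    def test_never_exceeds_largest_component(self, ds, data):
        rs = data.draw(
            st.lists(st.integers(1, 5), min_size=len(ds), max_size=len(ds))
        )
        D = nf.overall_desirability(ds, rs)
        assert min(ds) - 1e-12 <= D <= max(ds) + 1e-12

    def test_empty_lists_rejected(self):
        with pytest.raises(GoalError):
            nf.overall_desirability([], [])


class TestOptimizeDesirability:
    def test_concave_paraboloid_vertex_recovered(self, factors):
        # y = 10 - (x1-0.2)^2 - (x2+0.3)^2 - x3^2, unique interior maximum
        coefs = np.array(
            [10 - 0.04 - 0.09, 0.4, -0.6, 0.0, 0.0, 0.0, 0.0, -1.0, -1.0, -1.0]
        )
        spec = nf.SurfaceSpec(factors=factors, true_coefficients={"y": coefs})
        model = nf.fit_quadratic(nf.simulate_design_responses(spec), "y")
        goal = nf.Goal("y", "maximize", 0.0, 10.0)
        best = nf.optimize_desirability([model], [goal], n_starts=16, seed=3)[0]
        vertex = np.array([0.2, -0.3, 0.0])
        assert np.allclose(best.coded_settings, vertex, atol=1e-3)

    def test_study_goals_drive_ee_to_upper_limit(self, size_model, ee_model, goals):
        best = nf.optimize_desirability([size_model, ee_model], goals, 64, seed=0)[0]
        assert best.predicted["ee"] == pytest.approx(75.6, abs=0.25)
        assert 139.0 <= best.predicted["particle_size"] <= 142.5
        assert best.actual_settings["poloxamer"] >= 1.3

    def test_seed_insensitive_at_64_starts(self, size_model, ee_model, goals):
        models = [size_model, ee_model]
        d_values = [
            nf.optimize_desirability(models, goals, 64, seed=s)[0].overall_D
            for s in (0, 1, 2)
        ]
        assert max(d_values) - min(d_values) < 1e-3

    def test_solutions_within_bounds_and_recomputable(self, size_model, ee_model, goals):
        solutions = nf.optimize_desirability([size_model, ee_model], goals, 32, seed=5)
        factors = {f.name: f for f in size_model.factors}
        for sol in solutions:
            for name, value in sol.actual_settings.items():
                f = factors[name]
                assert f.low - 1e-9 <= value <= f.high + 1e-9
            for g in goals:
                if g.target_name in sol.predicted:
                    assert sol.individual_d[g.target_name] == pytest.approx(
                        nf.individual_desirability(sol.predicted[g.target_name], g),
                        abs=1e-12,
                    )
            assert 0.0 <= sol.overall_D <= 1.0

    def test_coarse_grid_cross_check(self, size_model, ee_model, goals):
        models = [size_model, ee_model]
        best = nf.optimize_desirability(models, goals, 64, seed=0)[0]
        axes = np.linspace(-1, 1, 41)
        grid = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), -1).reshape(-1, 3)
        grid_best = desirability_at(models, goals, grid).max()
        assert best.overall_D >= grid_best - 1e-6

    def test_unknown_goal_target_rejected(self, size_model, goals):
        bad = [nf.Goal("zeta", "minimize", -30.0, 0.0)]
        with pytest.raises(GoalError, match="names neither"):
            nf.optimize_desirability([size_model], bad, 4, seed=0)


class TestDesignSpace:
    def test_overlay_contains_reported_optimum(self, size_model, ee_model):
        constraints = [("particle_size", "<=", 141.0), ("ee", ">=", 75.5)]
        ds = nf.design_space([size_model, ee_model], constraints, grid_resolution=21)
        assert ds.mask.any()
        assert 0.0 < ds.feasible_fraction < 1.0
        # first reported solution (PLGA 72.1, lecithin 86.8, poloxamer 1.5)
        assert feasible_at([size_model, ee_model], constraints, (72.1, 86.8, 1.5))

    def test_impossible_constraint_empty_mask(self, size_model):
        ds = nf.design_space([size_model], [("particle_size", "<=", 0.0)], 11)
        assert not ds.mask.any()
        assert ds.feasible_fraction == 0.0

    def test_volume_fraction_stable_under_refinement(self, size_model, ee_model):
        constraints = [("particle_size", "<=", 150.0), ("ee", ">=", 70.0)]
        coarse = nf.design_space([size_model, ee_model], constraints, 21)
        fine = nf.design_space([size_model, ee_model], constraints, 101)
        assert abs(coarse.feasible_fraction - fine.feasible_fraction) < 0.05

    def test_frame_export_shape(self, size_model):
        ds = nf.design_space([size_model], [("particle_size", "<=", 160.0)], 5)
        frame = ds.to_frame()
        assert len(frame) == 5**3
        assert set(frame.columns) == {"PLGA", "lecithin", "poloxamer", "feasible"}

    def test_bad_constraint_rejected(self, size_model):
        with pytest.raises(GoalError):
            nf.design_space([size_model], [("particle_size", "<", 150.0)], 5)
        with pytest.raises(GoalError):
            nf.design_space([size_model], [("zeta", "<=", 0.0)], 5)
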