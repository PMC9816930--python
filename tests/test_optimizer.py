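"""The fortification LP: construction, solving, min-cap search, oracles."""

import numpy as np
import pytest

import fortiplan as fp
from fortiplan.optimizer import InfeasibleError

from conftest import toy_aggregates, toy_targets


class TestBuild:
    def test_contribution_coefficient_is_energy_over_ten(self):
        agg = toy_aggregates([[4.0]], [2.0])
        model = fp.build_lp(agg, fp.Scenario(name="x", cap_ug_per_10mj=25, allowed_groups=["g0"]),
                            toy_targets(["s0"]))
        assert model.contribution[0, 0] == pytest.approx(0.4)

    def test_disallowed_group_gets_no_variable(self):
        agg = toy_aggregates([[4.0, 3.0]], [2.0])
        model = fp.build_lp(agg, fp.Scenario(name="x", cap_ug_per_10mj=25, allowed_groups=["g1"]),
                            toy_targets(["s0"]))
        assert model.group_ids == ["g1"]
        assert model.energy_mj.shape == (1, 1)

    def test_matrix_shape_strata_by_groups(self):
        rng = np.random.default_rng(0)
        agg = toy_aggregates(rng.uniform(0.5, 3, size=(6, 5)), rng.uniform(1, 3, size=6))
        model = fp.build_lp(
            agg, fp.Scenario(name="x", cap_ug_per_10mj=25, allowed_groups=[f"g{j}" for j in range(5)]),
            toy_targets([f"s{i}" for i in range(6)]))
        assert model.energy_mj.shape == (6, 5)
        assert len(model.stratum_ids) == 6

    def test_dead_group_warns(self):
        agg = toy_aggregates([[4.0, 0.0]], [2.0])
        with pytest.warns(UserWarning, match="g1"):
            fp.build_lp(agg, fp.Scenario(name="x", cap_ug_per_10mj=25, allowed_groups=["g0", "g1"]),
                        toy_targets(["s0"]))


class TestSolve:
    def test_single_group_closed_form(self):
        """One group, E=4 MJ, B=2, RI=10: f* = 10(RI−B)/E = 20 with zero
        overshoot."""
        agg = toy_aggregates([[4.0]], [2.0])
        scheme = fp.solve_scheme(fp.build_lp(
            agg, fp.Scenario(name="x", cap_ug_per_10mj=25, allowed_groups=["g0"]),
            toy_targets(["s0"])))
        assert scheme.feasible
        assert scheme.levels_ug_per_10mj["g0"] == pytest.approx(20.0, abs=1e-8)
        assert scheme.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_cap_below_requirement_is_infeasible(self):
        agg = toy_aggregates([[4.0]], [2.0])
        scheme = fp.solve_scheme(fp.build_lp(
            agg, fp.Scenario(name="x", cap_ug_per_10mj=15, allowed_groups=["g0"]),
            toy_targets(["s0"])))
        assert not scheme.feasible
        assert scheme.levels_ug_per_10mj == {}

    def test_attainment_holds_in_both_objective_modes(self):
        rng = np.random.default_rng(3)
        agg = toy_aggregates(rng.uniform(0.3, 2.5, size=(4, 3)), rng.uniform(1, 4, size=4))
        targets = toy_targets([f"s{i}" for i in range(4)])
        for mode in ("sum_overshoot", "max_overshoot"):
            scheme = fp.solve_scheme(fp.build_lp(
                agg, fp.Scenario(name=mode, cap_ug_per_10mj=40, allowed_groups=["g0", "g1", "g2"],
                                 objective_mode=mode), targets))
            assert scheme.feasible
            assert all(v >= 10.0 - 1e-6 for v in scheme.modelled_intake_ug.values())

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_lp_matches_grid_oracle_on_2group_instances(self, seed):
        """Exhaustive 0.01-step grid search agrees with the LP objective
        within the grid's Lipschitz resolution on random 2×2 instances."""
        rng = np.random.default_rng(seed)
        energy = rng.uniform(0.5, 4.0, size=(2, 2))
        background = rng.uniform(1.0, 5.0, size=2)
        agg = toy_aggregates(energy, background)
        scenario = fp.Scenario(name="g", cap_ug_per_10mj=float(rng.integers(15, 41)),
                               allowed_groups=["g0", "g1"])
        targets = toy_targets(["s0", "s1"])
        step = 0.01
        lp = fp.solve_scheme(fp.build_lp(agg, scenario, targets))
        grid = fp.brute_force_scheme_oracle(agg, scenario, targets, grid_step=step)
        assert lp.feasible == grid.feasible
        if lp.feasible:
            # snapping the LP solution to the grid moves each f_g by < step,
            # changing the sum-overshoot objective by at most this bound
            lipschitz = step * energy.sum() / 10.0
            assert grid.objective_value >= lp.objective_value - 1e-9
            assert grid.objective_value - lp.objective_value <= lipschitz + 1e-9

    def test_grid_oracle_refuses_large_instances(self):
        agg = toy_aggregates(np.ones((1, 4)), [1.0])
        with pytest.raises(ValueError, match="3 groups"):
            fp.brute_force_scheme_oracle(
                agg, fp.Scenario(name="x", cap_ug_per_10mj=10,
                                 allowed_groups=["g0", "g1", "g2", "g3"]),
                toy_targets(["s0"]))


class TestMinCap:
    def test_threshold_of_closed_form(self):
        agg = toy_aggregates([[4.0]], [2.0])
        cap, scheme = fp.find_min_cap(agg, ["g0"], toy_targets(["s0"]), start=10)
        assert cap == 20
        assert scheme.feasible

    def test_returns_start_when_already_feasible(self):
        agg = toy_aggregates([[10.0]], [5.0])  # needs f = 5 < 10
        cap, _ = fp.find_min_cap(agg, ["g0"], toy_targets(["s0"]), start=10)
        assert cap == 10

    def test_bisection_agrees_with_sweep(self):
        rng = np.random.default_rng(5)
        agg = toy_aggregates(rng.uniform(0.3, 2, size=(5, 4)), rng.uniform(1, 4, size=5))
        groups = [f"g{j}" for j in range(4)]
        targets = toy_targets([f"s{i}" for i in range(5)])
        cap_sweep, _ = fp.find_min_cap(agg, groups, targets, start=1)
        cap_bisect, _ = fp.find_min_cap(agg, groups, targets, start=1, bisect=True)
        assert cap_sweep == cap_bisect

    def test_feasibility_monotone_in_cap(self):
        """Once feasible, feasibility persists for every larger cap."""
        agg = toy_aggregates([[3.0], [4.0]], [2.0, 3.0])
        targets = toy_targets(["s0", "s1"])
        seen_feasible = False
        for cap in range(1, 41):
            scheme = fp.solve_scheme(fp.build_lp(
                agg, fp.Scenario(name="c", cap_ug_per_10mj=cap, allowed_groups=["g0"]), targets))
            if seen_feasible:
                assert scheme.feasible, f"feasibility lost at cap {cap}"
            seen_feasible = seen_feasible or scheme.feasible
        assert seen_feasible

    def test_infeasible_range_reports_worst_stratum(self):
        agg = toy_aggregates([[0.1], [1.0]], [1.0, 1.0])
        with pytest.raises(InfeasibleError, match="s0"):
            fp.find_min_cap(agg, ["g0"], toy_targets(["s0", "s1"]), start=10, cap_max=20)


class TestSafetyByConstruction:
    def test_total_added_bounded_by_cap_times_energy(self, aggregates, targets):
        """For any solved scheme, a consumer drawing all energy E_tot from
        fortified foods gains at most C·E_tot/10 µg: every level obeys the
        common cap."""
        C = 40.0
        scenario = fp.Scenario(name="s", cap_ug_per_10mj=C,
                               allowed_groups=["milk", "cheese", "cereals", "fats", "juice"])
        scheme = fp.solve_scheme(fp.build_lp(aggregates, scenario, targets))
        assert scheme.feasible
        assert all(0 - 1e-9 <= v <= C + 1e-9 for v in scheme.levels_ug_per_10mj.values())
        e_tot = 10.0  # MJ/day, hypothetical all-fortified diet
        added = max(scheme.levels_ug_per_10mj.values()) * e_tot / 10.0
        assert added <= C * e_tot / 10.0 + 1e-9
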