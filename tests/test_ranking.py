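import numpy as np
import pytest

import evofit as ef
from evofit.grid import DensityField, StrategyGrid, SubsetIndicator
from evofit.ranking import (
    ExtinctionError,
    detect_selection,
    fitness_landscape,
    rank_pair,
    ranking_consistency_check,
    time_average_fitness,
)


def replicator_atom_field(mu0, horizon):
    """Map a replicator run onto a 3-atom strategy grid (one node per species)."""
    traj = ef.simulate_replicator(mu0, horizon, n_out=800)
    grid = StrategyGrid.atoms([0.0, 0.5, 1.0])
    return DensityField(grid, traj.times, traj.states)


class TestDetectSelection:
    def test_tradeoff_run_selects_the_fitness_maximiser(self, example3_field):
        A = ef.neighbourhood(example3_field.grid, 1.0, 0.05)
        selected, trace = detect_selection(example3_field, A, tolerance=1e-3)
        assert selected
        assert trace.measure_complement.iloc[-1] < 1e-3

    def test_full_grid_is_trivially_selected(self, example3_field):
        A = SubsetIndicator.full(example3_field.grid)
        selected, trace = detect_selection(example3_field, A)
        assert selected
        assert trace.measure_complement.iloc[-1] == 0.0

    def test_set_away_from_the_concentration_point_is_not_selected(self, grid201):
        # closed-form pathology run: mass escapes towards v = 0
        times = np.array([100.0, 500.0, 1000.0, 2000.0])
        vals = np.column_stack(
            [ef.example2_closed_form(grid201.nodes, t, grid=grid201) for t in times]
        )
        field = DensityField(grid201, times, vals)
        A = SubsetIndicator.interval(grid201, 0.1, 1.0)
        selected, trace = detect_selection(field, A, tolerance=1e-3)
        assert not selected
        assert trace.measure_A.iloc[-1] < 1e-3  # A itself dies out

    def test_whole_population_extinction_is_an_error(self, grid101):
        times = np.array([0.0, 1.0, 2.0])
        vals = np.outer(np.ones(101), [1.0, 1e-8, 1e-12])
        field = DensityField(grid101, times, vals)
        with pytest.raises(ExtinctionError):
            detect_selection(field, SubsetIndicator.interval(grid101, 0.0, 0.5), 1e-3)


class TestRankPair:
    def test_fitness_maximiser_beats_the_minimiser(self, example3_field):
        rep = rank_pair(example3_field, 1.0, 0.0)
        assert rep.verdict == "v_better"
        assert rep.converged

    def test_antisymmetry_under_swap(self, example3_field):
        fwd = rank_pair(example3_field, 1.0, 0.0)
        rev = rank_pair(example3_field, 0.0, 1.0)
        assert rev.verdict == "w_better"
        assert fwd.swapped().verdict == rev.verdict

    def test_identical_strategies_are_incomparable(self, example3_field):
        assert rank_pair(example3_field, 0.5, 0.5).verdict == "incomparable"

    def test_zero_initial_neighbourhood_measure_is_a_precondition_error(self, grid101):
        vals = np.ones((101, 2))
        vals[:5, :] = 0.0
        field = DensityField(grid101, [0.0, 1.0], vals)
        with pytest.raises(ValueError, match="mu-nonzero"):
            rank_pair(field, 0.5, 0.0)

    def test_coexisting_replicator_strategies_are_incomparable(self):
        field = replicator_atom_field([0.2, 0.3, 0.5], 2000.0)
        for v, w in [(0.0, 0.5), (0.5, 1.0), (0.0, 1.0)]:
            assert rank_pair(field, v, w, radius=0.1).verdict == "incomparable"

    def test_face_verdicts_are_cyclic_across_initial_conditions(self):
        # each face run yields one verdict; combined they break transitivity,
        # showing that the ranking order depends on the initial condition
        runs = {
            (0.0, 0.5, 0.5): (0.5, 1.0),  # v2 beats v3
            (0.5, 0.0, 0.5): (1.0, 0.0),  # v3 beats v1
            (0.5, 0.5, 0.0): (0.0, 0.5),  # v1 beats v2
        }
        reports = []
        for mu0, (v, w) in runs.items():
            field = replicator_atom_field(list(mu0), 30000.0)
            rep = rank_pair(field, v, w, radius=0.1, tolerance=1e-3,
                            initial_state=np.array(mu0))
            assert rep.verdict == "v_better", mu0
            reports.append(rep)
        ok, violations = ranking_consistency_check(reports)
        assert not ok and any("transitivity" in v for v in violations)
        for rep in reports:  # each single-run report is internally consistent
            assert ranking_consistency_check([rep])[0]


class TestTimeAverageFitness:
    def test_exponential_trajectory_recovers_its_rate(self, grid101):
        times = np.linspace(0.0, 10.0, 51)  # window endpoints on stored times
        c = 0.37
        vals = np.tile(np.exp(c * times), (101, 1))
        field = DensityField(grid101, times, vals, bound=np.inf)
        est = time_average_fitness(field, 0.5, (2.0, 10.0))
        assert est.J1 == pytest.approx(c, abs=1e-12)
        assert est.converged

    def test_winner_growth_rate_vanishes_at_selection_equilibrium(self, example3_field):
        est = time_average_fitness(example3_field, 1.0, (250.0, 500.0))
        assert abs(est.J1) < 1e-2

    def test_loser_rate_equals_its_fitness_deficit(self, example3_field):
        # k(0)/r(0) - max k/r = 1 - 2 = -1 once the integral term settles
        est = time_average_fitness(example3_field, 0.0, (250.0, 500.0))
        assert est.J1 == pytest.approx(-1.0, abs=1e-2)

    def test_zero_density_in_window_is_an_error(self, grid101):
        vals = np.ones((101, 2))
        vals[10, :] = 0.0
        field = DensityField(grid101, [0.0, 1.0], vals)
        with pytest.raises(ValueError, match="undefined"):
            time_average_fitness(field, grid101.nodes[10], (0.0, 1.0))


class TestFitnessLandscape:
    def test_argmax_matches_the_coefficient_ratio_argmax(self, lq_eta_field):
        from evofit.synthetic import tradeoff_family

        fam = tradeoff_family("linear-quadratic")
        grid = lq_eta_field.grid
        expected = grid.nodes[np.argmax(fam.ratio(grid.nodes))]
        scape = fitness_landscape(lq_eta_field, window=(250.0, 500.0))
        assert scape.argmax == pytest.approx([expected])
        assert abs(scape.max_J1) < 1e-2

    def test_constant_field_is_flat_with_zero_fitness(self, grid101):
        times = np.linspace(0.0, 100.0, 11)
        field = DensityField(grid101, times, np.ones((101, 11)))
        scape = fitness_landscape(field)
        assert np.allclose(scape.frame.J1, 0.0, atol=1e-12)
        assert scape.argmax.size == grid101.n_nodes  # polymorphic maximum

    def test_landscape_order_agrees_with_pairwise_verdicts(self, example3_field):
        scape = fitness_landscape(example3_field, window=(250.0, 500.0))
        f = scape.frame.set_index("v").J1
        for v, w in [(1.0, 0.0), (0.8, 0.2), (1.0, 0.5)]:
            assert f[v] > f[w] + 0.05
            assert rank_pair(example3_field, v, w).verdict == "v_better"

    def test_face_replicator_fitness_orders_the_survivor_first(self):
        field = replicator_atom_field([0.0, 0.5, 0.5], 2000.0)
        J2 = time_average_fitness(field, 0.5, (1000.0, 2000.0)).J1
        J3 = time_average_fitness(field, 1.0, (1000.0, 2000.0)).J1
        assert J2 > J3


class TestConsistencyCheck:
    def test_empty_report_set_is_consistent(self):
        assert ranking_consistency_check([]) == (True, [])

    def test_transitive_chain_from_three_node_landscape(self, grid101):
        # three strategies with k/r = 2, 1.5, 1: verdicts must form a chain
        grid = StrategyGrid.atoms([0.0, 0.5, 1.0])
        model = ef.tradeoff_model(grid, k=lambda v: 2.0 - v)
        field = ef.simulate_nonlocal_logistic(model, 60.0)
        reports = [
            rank_pair(field, v, w, radius=0.1)
            for v, w in [(0.0, 0.5), (0.5, 1.0), (0.0, 1.0)]
        ]
        assert [r.verdict for r in reports] == ["v_better"] * 3
        assert ranking_consistency_check(reports)[0]

    def test_corrupted_verdict_set_reports_violation(self, example3_field):
        good = rank_pair(example3_field, 1.0, 0.0)
        bad = rank_pair(example3_field, 0.0, 1.0)
        bad.verdict = "v_better"  # corrupt: claims 0 beats 1 as well
        ok, violations = ranking_consistency_check([good, bad])
        assert not ok and any("symmetric" in v for v in violations)
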