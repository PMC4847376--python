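"""Unit tests of the simulation engine's operations and contracts."""

import math

import numpy as np
import pytest

import estg
from estg import (
    SimulationError,
    SimulationState,
    apply_conditional_transitions,
    compute_propensities,
    fire_event,
    run,
    run_batch,
    sample_next_event,
    translate_rules,
    update_global_parameters,
)

from conftest import (
    ScriptedRNG,
    critical_sc_xml,
    load_fixture,
    make_program,
    pure_birth_xml,
    single_death_xml,
)


class TestTranslateRules:
    def test_channel_rates_are_rate_times_probability(self):
        p = load_fixture("stem_cell_ms")
        channels = translate_rules(p)
        rates = [(c.rule_index, c.outcome_index, c.rate_c) for c in channels]
        assert rates == [
            (0, 0, pytest.approx(0.05)),
            (0, 1, pytest.approx(0.05)),
            (1, 0, pytest.approx(0.49)),
            (1, 1, pytest.approx(0.51)),
        ]

    def test_single_outcome_channel_carries_full_rate(self):
        p = make_program(
            "<Program><ExecParams><SimTime>1</SimTime></ExecParams>"
            "<Rule><Name>A</Name><Rate>2</Rate>"
            "<Prod><Products>A,A</Products><Prob>1</Prob></Prod></Rule>"
            "</Program>"
        )
        (ch,) = translate_rules(p)
        assert ch.rate_c == 2.0

    def test_channel_sum_equals_rule_rate(self):
        for name in ("stem_cell_ms", "conditional_toy", "lotka_volterra"):
            p = load_fixture(name)
            channels = translate_rules(p)
            for i, rule in enumerate(p.rules):
                total = sum(c.rate_c for c in channels if c.rule_index == i)
                assert total == pytest.approx(rule.rate, abs=1e-12)


class TestPropensities:
    def test_product_of_channel_rate_and_population(self):
        p = load_fixture("stem_cell_ms")
        channels = translate_rules(p)
        props = compute_propensities(channels, {"SC": 0, "Diff": 100})
        assert props == pytest.approx([0.0, 0.0, 49.0, 51.0])

    def test_all_extinct_gives_zero_vector(self):
        p = load_fixture("stem_cell_ms")
        channels = translate_rules(p)
        assert compute_propensities(channels, {"SC": 0, "Diff": 0}) == [0, 0, 0, 0]

    def test_negative_population_is_a_consistency_error(self):
        p = load_fixture("stem_cell_ms")
        channels = translate_rules(p)
        with pytest.raises(SimulationError):
            compute_propensities(channels, {"SC": -1, "Diff": 0})


class TestDirectMethodSampling:
    def test_waiting_time_closed_form(self):
        rng = ScriptedRNG(uniforms=[0.5, 0.0])
        tau, j = sample_next_event([2.0], rng)
        assert tau == pytest.approx(math.log(2) / 2)
        assert j == 0

    def test_channel_selected_by_cumulative_propensity(self):
        tau, j = sample_next_event([1.0, 3.0], ScriptedRNG(uniforms=[0.5, 0.1]))
        assert j == 0
        tau, j = sample_next_event([1.0, 3.0], ScriptedRNG(uniforms=[0.5, 0.9]))
        assert j == 1

    def test_zero_propensity_channel_is_unreachable(self):
        for u2 in np.linspace(0.001, 0.999, 97):
            _, j = sample_next_event([5.0, 0.0, 5.0], ScriptedRNG([0.5, u2]))
            assert j != 1

    def test_zero_total_propensity_signals_extinction(self):
        assert sample_next_event([0.0, 0.0], ScriptedRNG()) is None


class TestFireEvent:
    def test_differentiation_applies_child_state_updaters(self):
        p = load_fixture("stem_cell_ms")
        state = SimulationState(p, seed=3)
        diff_channel = next(
            c for c in state.channels if c.lhs == "SC" and c.outcome_index == 1
        )
        event = fire_event(state, diff_channel, state.rng)
        parent = state.forest.nodes[event.parent_node]
        assert parent.end_cause == "division"
        assert len(event.child_nodes) == 2
        for cid in event.child_nodes:
            child = state.forest.nodes[cid]
            assert child.species == "Diff"
            # Gen is new on Diff: initialized, not updated
            assert child.states["Gen"] == (1.0,)
            # MS inherited through the stepwise mutation model: +-1 steps
            deltas = np.array(child.states["MS"]) - np.array(parent.states["MS"])
            assert set(deltas).issubset({-1.0, 0.0, 1.0})

    def test_death_outcome_closes_node_without_children(self):
        p = load_fixture("stem_cell_ms")
        state = SimulationState(p, seed=3)
        # place one Diff individual by firing a differentiation first
        fire_event(state, state.channels[1], state.rng)
        n_diff = state.counts["Diff"]
        death = next(
            c for c in state.channels if c.lhs == "Diff" and c.outcome_index == 1
        )
        event = fire_event(state, death, state.rng)
        assert event.child_nodes == ()
        assert state.forest.nodes[event.parent_node].end_cause == "death"
        assert state.counts["Diff"] == n_diff - 1

    def test_zero_change_probability_copies_ms_vector(self):
        xml = (
            "<Program><ExecParams><SimTime>1</SimTime></ExecParams>"
            "<Rule><Name>A</Name><InitPop>1</InitPop><Rate>1</Rate>"
            "<Prod><Products>A,A</Products><Prob>1</Prob></Prod>"
            "<InternalState><Name>MS</Name><InitVal>10</InitVal>"
            "<FuncName>zero_ms</FuncName><DupNum>2</DupNum></InternalState>"
            "</Rule></Program>"
        )
        reg = estg.UpdaterRegistry()
        reg.register("zero_ms", "state", estg.updaters.make_ms_step(0.0))
        p = estg.validate_program(estg.parse_program(xml), reg)
        state = SimulationState(p, seed=1, registry=reg)
        root = state.forest.nodes[1]
        root.states = {"MS": (10.0, 12.0)}
        event = fire_event(state, state.channels[0], state.rng)
        for cid in event.child_nodes:
            assert state.forest.nodes[cid].states["MS"] == (10.0, 12.0)


class TestConditionalTransitions:
    def _toy_state(self):
        return SimulationState(load_fixture("conditional_toy"), seed=1)

    def test_counter_above_threshold_transforms_with_carry_over(self):
        state = self._toy_state()
        scsym = next(n for n in state.forest.nodes.values() if n.species == "SCSym")
        scsym.states = {"CounterStoch": (5.7,)}
        state.pending_check.append(scsym.node_id)
        transforms = apply_conditional_transitions(state)
        assert transforms == [(scsym.node_id, "SCSym", "Diff")]
        (child_id,) = state.forest.nodes[scsym.node_id].children
        child = state.forest.nodes[child_id]
        assert child.species == "Diff"
        assert child.states["CounterStoch"] == (5.7,)
        assert state.forest.nodes[scsym.node_id].end_cause == "transform"

    def test_termination_target_kills_without_child(self):
        state = self._toy_state()
        scsym = next(n for n in state.forest.nodes.values() if n.species == "SCSym")
        scsym.states = {"CounterStoch": (10.2,)}
        scsym.species = "Diff"
        state.living["SCSym"].remove(scsym.node_id)
        state.living["Diff"].add(scsym.node_id)
        state.counts["SCSym"] -= 1
        state.counts["Diff"] += 1
        state.pending_check.append(scsym.node_id)
        transforms = apply_conditional_transitions(state)
        assert transforms == [(scsym.node_id, "Diff", None)]
        assert state.forest.nodes[scsym.node_id].end_cause == "death"
        assert state.forest.nodes[scsym.node_id].children == []

    def test_no_condition_satisfied_is_a_no_op(self):
        state = self._toy_state()
        before = dict(state.counts)
        assert apply_conditional_transitions(state) == []
        assert state.counts == before


class TestGlobalUpdates:
    def test_lotka_volterra_parameters_at_initial_populations(self):
        state = SimulationState(load_fixture("lotka_volterra"), seed=1)
        # applied once at t=0: r1 = c1 + c2*|Predator| = 10 + 0.01*900
        assert state.rates == pytest.approx([19.0, 19.0])
        assert state.probs[0][0] == pytest.approx(10.0 / 19.0)
        assert state.probs[1][0] == pytest.approx(9.0 / 19.0)
        for i, rule in enumerate(state.program.rules):
            total = sum(
                c.rate_c for c in state.channels if c.rule_index == i
            )
            assert total == pytest.approx(state.rates[i], abs=1e-12)

    def test_empty_updater_leaves_parameters_unchanged(self):
        state = SimulationState(load_fixture("stem_cell_ms"), seed=1)
        assert state.rates == [0.1, 1.0]
        assert state.probs == [[0.5, 0.5], [0.49, 0.51]]

    def test_invalid_probability_sum_aborts_with_rule_name(self):
        p = make_program(pure_birth_xml())
        state = SimulationState(p, seed=1)
        state.global_updater = lambda pops, t, const: {"A": (1.0, [0.7])}
        state.probs = [[0.5]]  # force a length match but a bad sum
        with pytest.raises(SimulationError, match="A"):
            update_global_parameters(state)

    def test_negative_rate_aborts(self):
        p = make_program(pure_birth_xml())
        state = SimulationState(p, seed=1)
        state.global_updater = lambda pops, t, const: {"A": (-1.0, [1.0])}
        with pytest.raises(SimulationError, match="rate"):
            update_global_parameters(state)

    def test_legacy_first_update_keeps_placeholders_until_first_event(self):
        p = load_fixture("lotka_volterra")
        eager = SimulationState(p, seed=1)
        legacy = SimulationState(p, seed=1, legacy_first_update=True)
        assert legacy.rates == [1.0, 1.0]  # file placeholders
        assert eager.rates == pytest.approx([19.0, 19.0])


class TestRun:
    def test_single_individual_death(self):
        result = run(make_program(single_death_xml()), seed=5)
        assert len(result.events) == 1
        assert result.end_reason == "extinction"
        forest = result.forest
        assert len(forest) == 1
        assert forest.nodes[1].end_cause == "death"

    def test_replay_is_bit_identical(self):
        p = load_fixture("conditional_toy")
        a = run(p, seed=11)
        b = run(p, seed=11)
        assert [e.time for e in a.events] == [e.time for e in b.events]
        assert [e.channel for e in a.events] == [e.channel for e in b.events]
        assert a.channel_counts == b.channel_counts
        assert len(a.forest) == len(b.forest)
        for nid, node in a.forest.nodes.items():
            other = b.forest.nodes[nid]
            assert (node.species, node.birth_time, node.end_time,
                    node.end_cause, node.states) == (
                other.species, other.birth_time, other.end_time,
                other.end_cause, other.states)

    def test_no_event_recorded_past_span(self):
        result = run(make_program(pure_birth_xml(sim_time=1.0)), seed=2)
        assert result.end_reason == "span-exhausted"
        assert all(e.time <= 1.0 for e in result.events)
        assert result.end_time == 1.0

    def test_conservation_checked_at_every_event(self):
        # check_invariants recounts the forest after each event
        result = run(load_fixture("conditional_toy"), seed=3, t_span=60,
                     check_invariants=True)
        assert result.events

    def test_final_series_matches_forest_counts(self):
        result = run(load_fixture("stem_cell_ms"), seed=9)
        from estg import living_population

        final = living_population(result.forest, result.end_time)
        for sp in result.rule_names:
            assert final.get(sp, 0) == result.population_series[sp][-1]


class TestRunBatch:
    def test_one_result_per_seed_in_order(self):
        p = make_program(pure_birth_xml(init=5, sim_time=1.0))
        results = run_batch(p, seeds=range(10))
        assert [r.seed for r in results] == list(range(10))
        logs = {tuple(e.time for e in r.events) for r in results}
        assert len(logs) > 1  # different seeds explore different histories

    def test_duplicate_seeds_warn_and_match(self):
        p = make_program(pure_birth_xml(init=5, sim_time=1.0))
        with pytest.warns(UserWarning, match="duplicate"):
            a, b = run_batch(p, seeds=[7, 7])
        assert [e.time for e in a.events] == [e.time for e in b.events]

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            run_batch(make_program(pure_birth_xml()), seeds=[])


class TestCriticalBranchingStructure:
    def test_inert_species_never_fires(self):
        result = run(make_program(critical_sc_xml(init=5, sim_time=5.0)), seed=4)
        assert result.rule_counts()["Diff"] == 0
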