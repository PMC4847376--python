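"""Exact stochastic simulation of a validated program.

Each rule ``A --r--> {S1}_p1 | ... | {Sn}_pn`` is translated into ``n``
reaction channels with rates ``c_i = r * p_i``; channel propensities are
``c_i * |A|`` and the next event (waiting time and channel identity) is drawn
with the Gillespie Direct Method.  Firing a channel closes one uniformly
chosen individual of the left-hand species and creates its children, applying
each internal state's updating function per child and per dup instance.
After every event all living individuals of species with conditional
transitions are examined once, and the global updating function (if any)
rewrites rates and probabilities from the new system state.

The full history is recorded: an event log, per-channel firing counts, the
per-species population step function and the complete lineage forest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .lineage import LineageForest
from .program_model import (
    Program,
    UpdaterRegistry,
    builtin_registry,
    validate_program,
)

__all__ = [
    "SimulationError",
    "ReactionChannel",
    "EventRecord",
    "RunResult",
    "SimulationState",
    "translate_rules",
    "compute_propensities",
    "sample_next_event",
    "fire_event",
    "apply_conditional_transitions",
    "update_global_parameters",
    "run",
    "run_batch",
]

_PROB_TOL = 1e-9


class SimulationError(RuntimeError):
    """Internal consistency breach or invalid updater output during a run."""


@dataclass(frozen=True, slots=True)
class ReactionChannel:
    """One (rule, outcome) pair; the unit of Gillespie sampling."""

    rule_index: int
    outcome_index: int
    rate_c: float
    lhs: str


@dataclass(slots=True)
class EventRecord:
    """One fired reaction plus the conditional transforms it triggered."""

    time: float
    channel: tuple[int, int]
    parent_node: int
    child_nodes: tuple[int, ...]
    #: (node_id, source species, target species or None for termination)
    conditional_transforms: list[tuple[int, str, str | None]] = field(
        default_factory=list
    )


@dataclass
class RunResult:
    """Complete history of one seeded execution."""

    seed: int
    events: list[EventRecord]
    channel_counts: dict[tuple[int, int], int]
    times: np.ndarray
    population_series: dict[str, np.ndarray]
    forest: LineageForest
    end_time: float
    end_reason: str
    rule_names: tuple[str, ...]

    def series(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """Right-continuous population step function of one species."""
        if species not in self.population_series:
            raise KeyError(f"unknown species {species!r}")
        return self.times, self.population_series[species]

    def rule_counts(self) -> dict[str, int]:
        """Total firings per rule (channels summed within each rule)."""
        out = {name: 0 for name in self.rule_names}
        for (rule_i, _), n in self.channel_counts.items():
            out[self.rule_names[rule_i]] += n
        return out


class _Pop:
    """Indexed multiset of living node ids: O(1) add/remove/uniform choice."""

    __slots__ = ("ids", "pos")

    def __init__(self):
        self.ids: list[int] = []
        self.pos: dict[int, int] = {}

    def add(self, node_id: int) -> None:
        self.pos[node_id] = len(self.ids)
        self.ids.append(node_id)

    def remove(self, node_id: int) -> None:
        i = self.pos.pop(node_id)
        last = self.ids.pop()
        if i < len(self.ids):
            self.ids[i] = last
            self.pos[last] = i

    def choose(self, rng) -> int:
        return self.ids[int(rng.integers(len(self.ids)))]

    def __len__(self) -> int:
        return len(self.ids)


def translate_rules(program: Program) -> list[ReactionChannel]:
    """One channel per (rule, outcome) with ``c_i = r * p_i``, in rule order
    then outcome order."""
    if not program.validated:
        raise ValueError("program must be validated before translation")
    channels = []
    for rule_i, rule in enumerate(program.rules):
        for out_i, group in enumerate(rule.outcomes):
            channels.append(
                ReactionChannel(
                    rule_i, out_i, rule.rate * float(group.probability), rule.lhs
                )
            )
    return channels


def _build_channels(
    rates: list[float], probs: list[list[float]], lhs: list[str]
) -> list[ReactionChannel]:
    return [
        ReactionChannel(rule_i, out_i, rates[rule_i] * p, lhs[rule_i])
        for rule_i in range(len(rates))
        for out_i, p in enumerate(probs[rule_i])
    ]


def compute_propensities(
    channels: list[ReactionChannel], populations: dict[str, int]
) -> list[float]:
    """``a_j = c_j * |lhs species of channel j|``."""
    out = []
    for ch in channels:
        n = populations[ch.lhs]
        if n < 0:
            raise SimulationError(
                f"negative population {n} for species {ch.lhs!r}"
            )
        out.append(ch.rate_c * n)
    return out


def sample_next_event(propensities, rng):
    """Direct-Method draw: waiting time and channel index.

    Returns ``(tau, j)`` with ``tau = ln(1/u1)/a0`` and ``j`` the smallest
    index whose cumulative propensity exceeds ``u2 * a0``; consumes exactly
    two uniform draws.  Returns ``None`` when the total propensity is zero
    (no further events possible -- the caller halts).
    """
    a0 = 0.0
    for a in propensities:
        a0 += a
    if a0 <= 0.0:
        return None
    u1 = rng.random()
    while u1 <= 0.0:  # guard log(0); measure-zero event
        u1 = rng.random()
    tau = -math.log(u1) / a0
    target = rng.random() * a0
    cum = 0.0
    j_last = 0
    for j, a in enumerate(propensities):
        if a <= 0.0:
            continue
        cum += a
        j_last = j
        if cum > target:
            return tau, j
    return tau, j_last  # float round-off at the upper edge


# ---------------------------------------------------------------------------
# engine state
# ---------------------------------------------------------------------------

class SimulationState:
    """Mutable state of one execution; operated on by the public operations.

    Constructing the state creates the initial individuals (one lineage root
    each, internal states at their initial values) and, unless
    ``legacy_first_update`` is set, applies the global updater once at t = 0
    so that the first event is already sampled under environment-consistent
    parameters rather than the file's placeholder values.
    """

    def __init__(
        self,
        program: Program,
        seed: int | None = None,
        t_span: float | None = None,
        constants: dict | None = None,
        registry: UpdaterRegistry | None = None,
        legacy_first_update: bool = False,
    ):
        registry = registry or builtin_registry()
        if not program.validated:
            program = validate_program(program, registry)
        self.program = program
        self.constants = dict(constants or {})
        self.seed = program.exec_params.seed if seed is None else int(seed)
        self.t_span = (
            program.exec_params.sim_time if t_span is None else float(t_span)
        )
        if self.t_span <= 0:
            raise ValueError("t_span must be positive")
        self.rng = np.random.default_rng(self.seed)
        self.t = 0.0

        self.lhs = [r.lhs for r in program.rules]
        self.rule_index = {name: i for i, name in enumerate(self.lhs)}
        self.rates = [r.rate for r in program.rules]
        self.probs = [
            [float(g.probability) for g in r.outcomes] for r in program.rules
        ]
        self.channels = _build_channels(self.rates, self.probs, self.lhs)

        self.states_by_species = {
            sp: list(defs) for sp, defs in program.internal_states.items()
        }
        self.conditionals_by_species: dict[str, list] = {}
        for cond in program.conditionals:
            self.conditionals_by_species.setdefault(
                cond.source_species, []
            ).append(cond)
        # internal-state values never change over a node's life, so a
        # condition free of pop()/time()/normrnd() has a fixed outcome per
        # node and needs to be examined only when the node is created; the
        # sweep then reduces to newly created individuals without changing
        # the every-event-full-sweep semantics
        self._static_conditions = all(
            not c.compiled.dynamic for c in program.conditionals
        )
        self.pending_check: list[int] = []

        self.global_updater = (
            registry.resolve_global(program.global_updater_name)
            if program.global_updater_name
            else None
        )

        self.forest = LineageForest()
        self.living: dict[str, _Pop] = {sp: _Pop() for sp in self.lhs}
        self.counts: dict[str, int] = {sp: 0 for sp in self.lhs}
        for rule in program.rules:
            init_values = self._initial_states(rule.lhs)
            watched = rule.lhs in self.conditionals_by_species
            for _ in range(rule.initial_population):
                node_id = self.forest.new_node(rule.lhs, None, 0.0, init_values)
                self.living[rule.lhs].add(node_id)
                self.counts[rule.lhs] += 1
                if watched:
                    self.pending_check.append(node_id)

        self.events: list[EventRecord] = []
        self.channel_counts: dict[tuple[int, int], int] = {}
        self.series_times: list[float] = [0.0]
        self.series_counts: dict[str, list[int]] = {
            sp: [self.counts[sp]] for sp in self.lhs
        }

        if self.global_updater is not None and not legacy_first_update:
            update_global_parameters(self)

    def _initial_states(self, species: str):
        defs = self.states_by_species.get(species)
        if not defs:
            return None
        return {ist.name: (ist.init_value,) * ist.dup for ist in defs}

    def _expr_env(self):
        """Environment for expression updaters and conditions."""
        counts = self.counts
        t = self.t
        return {
            "pop": lambda name: counts.get(name, 0),
            "time": lambda: t,
        }

    def record_event(self, event: EventRecord) -> None:
        self.events.append(event)
        self.series_times.append(event.time)
        for sp in self.lhs:
            self.series_counts[sp].append(self.counts[sp])

    def assert_conservation(self) -> None:
        """Population counters must equal living-node counts in the forest."""
        actual: dict[str, int] = {sp: 0 for sp in self.lhs}
        for node in self.forest.nodes.values():
            if node.end_time is None:
                actual[node.species] += 1
        if actual != self.counts:
            raise SimulationError(
                f"conservation breach at t={self.t}: counters {self.counts} "
                f"vs forest {actual}"
            )


def _apply_state_updater(fn, x: float, rng, env: dict) -> float:
    if getattr(fn, "needs_env", False):
        return fn(x, rng, env)
    return fn(x, rng)


def fire_event(state: SimulationState, channel: ReactionChannel, rng) -> EventRecord:
    """Fire one channel: close a uniformly chosen individual of the rule's
    left-hand species and create the outcome group's children.

    Each child's internal-state instances are computed by that state's
    updater applied to the parent's corresponding value (independently per
    child and per dup instance); states the parent lacks start at their
    initial value.
    """
    rule = state.program.rules[channel.rule_index]
    group = rule.outcomes[channel.outcome_index]
    pool = state.living[channel.lhs]
    if len(pool) == 0:
        raise SimulationError(
            f"no living individual of {channel.lhs!r} despite positive "
            "propensity"
        )
    parent_id = pool.choose(rng)
    parent = state.forest.nodes[parent_id]

    cause = "division" if group.products else "death"
    state.forest.close(parent_id, state.t, cause)
    pool.remove(parent_id)
    state.counts[channel.lhs] -= 1

    env = state._expr_env()
    children = []
    parent_states = parent.states
    for sp in group.products:
        defs = state.states_by_species.get(sp)
        values = None
        if defs:
            values = {}
            for ist in defs:
                pvals = parent_states.get(ist.name) if parent_states else None
                if pvals is None:
                    values[ist.name] = (ist.init_value,) * ist.dup
                else:
                    fn = ist.updater
                    values[ist.name] = tuple(
                        _apply_state_updater(fn, pv, rng, env) for pv in pvals
                    )
        child_id = state.forest.new_node(sp, parent_id, state.t, values)
        state.living[sp].add(child_id)
        state.counts[sp] += 1
        if sp in state.conditionals_by_species:
            state.pending_check.append(child_id)
        children.append(child_id)

    key = (channel.rule_index, channel.outcome_index)
    state.channel_counts[key] = state.channel_counts.get(key, 0) + 1
    return EventRecord(
        time=state.t,
        channel=key,
        parent_node=parent_id,
        child_nodes=tuple(children),
    )


def apply_conditional_transitions(state: SimulationState):
    """One sweep over living individuals of species with conditionals.

    Individuals are visited in stable node-id order; the first conditional
    (in program order) whose condition holds is applied.  Transform children
    created during the sweep are not re-examined until the next event.
    Returns the list of applied ``(node_id, source, target)`` transforms.
    """
    if not state.conditionals_by_species:
        return []
    by_species = state.conditionals_by_species
    if state._static_conditions:
        # condition outcomes are fixed per node: only nodes created since
        # the previous sweep can newly satisfy one
        candidates = state.pending_check
        state.pending_check = []
    else:
        candidates = []
        for sp in by_species:
            candidates.extend(state.living[sp].ids)
        state.pending_check = []
    if not candidates:
        return []
    candidates.sort()

    base_env = state._expr_env()
    rng = state.rng
    base_env["normrnd"] = lambda mu, sigma: rng.normal(mu, sigma)
    transforms = []
    for node_id in candidates:
        node = state.forest.nodes[node_id]
        if node.end_time is not None:  # already transformed this sweep
            continue
        conds = by_species[node.species]
        env = dict(base_env)
        if node.states:
            for name, vals in node.states.items():
                env[name] = vals[0] if len(vals) == 1 else vals
        for cond in conds:
            if not cond.compiled.evaluate(env):
                continue
            source = node.species
            target = cond.target
            state.living[source].remove(node_id)
            state.counts[source] -= 1
            if target is None:
                state.forest.close(node_id, state.t, "death")
            else:
                state.forest.close(node_id, state.t, "transform")
                defs = state.states_by_species.get(target)
                values = None
                if defs:
                    values = {}
                    for ist in defs:
                        pvals = (
                            node.states.get(ist.name) if node.states else None
                        )
                        # shared states carry over unchanged; new states
                        # start at their initial value
                        values[ist.name] = (
                            pvals
                            if pvals is not None
                            else (ist.init_value,) * ist.dup
                        )
                child_id = state.forest.new_node(
                    target, node_id, state.t, values
                )
                state.living[target].add(child_id)
                state.counts[target] += 1
                if target in by_species:
                    # examined at the next event's sweep, not this one
                    state.pending_check.append(child_id)
            transforms.append((node_id, source, target))
            break
    return transforms


def update_global_parameters(state: SimulationState) -> None:
    """Invoke the global updater and rebuild the reaction channels.

    The updater receives (populations, time, user constants) and returns new
    ``(rate, probabilities)`` per rule lhs; outputs are re-validated (rate
    non-negative, probabilities summing to one) and the channel decomposition
    ``sum_i c_i = r`` is restored by rebuilding the channels.
    """
    fn = state.global_updater
    if fn is None:
        return
    out = fn(dict(state.counts), state.t, state.constants)
    if not out:
        return
    for lhs_name, payload in out.items():
        if lhs_name not in state.rule_index:
            raise SimulationError(
                f"global updater returned parameters for unknown rule "
                f"{lhs_name!r}"
            )
        rate, probs = payload
        i = state.rule_index[lhs_name]
        if not math.isfinite(rate) or rate < 0:
            raise SimulationError(
                f"global updater returned invalid rate {rate} for rule "
                f"{lhs_name!r}"
            )
        probs = [float(p) for p in probs]
        if len(probs) != len(state.probs[i]):
            raise SimulationError(
                f"global updater returned {len(probs)} probabilities for "
                f"rule {lhs_name!r}, expected {len(state.probs[i])}"
            )
        if any(p < -_PROB_TOL for p in probs) or abs(sum(probs) - 1.0) > _PROB_TOL:
            raise SimulationError(
                f"global updater returned probabilities {probs} for rule "
                f"{lhs_name!r} that do not form a distribution"
            )
        state.rates[i] = float(rate)
        state.probs[i] = probs
    state.channels = _build_channels(state.rates, state.probs, state.lhs)


# ---------------------------------------------------------------------------
# run loop
# ---------------------------------------------------------------------------

def run(
    program: Program,
    seed: int | None = None,
    t_span: float | None = None,
    *,
    constants: dict | None = None,
    registry: UpdaterRegistry | None = None,
    legacy_first_update: bool = False,
    max_events: int | None = None,
    check_invariants: bool = False,
) -> RunResult:
    """Execute one seeded simulation and return its complete history.

    ``seed`` and ``t_span`` default to the program's execution parameters.
    The same (program, seed, t_span) always yields a bit-identical result.
    ``max_events`` optionally bounds the event count (guard against runaway
    populations); when hit, the run is censored at the current time with
    ``end_reason = "event-cap"``.
    """
    state = SimulationState(
        program,
        seed=seed,
        t_span=t_span,
        constants=constants,
        registry=registry,
        legacy_first_update=legacy_first_update,
    )
    n_events = 0
    while True:
        props = compute_propensities(state.channels, state.counts)
        drawn = sample_next_event(props, state.rng)
        if drawn is None:
            end_reason = "extinction"
            end_time = state.t_span
            break
        tau, j = drawn
        if state.t + tau > state.t_span:
            # the tentative event falls beyond the span: discard it and stop
            end_reason = "span-exhausted"
            end_time = state.t_span
            break
        state.t += tau
        event = fire_event(state, state.channels[j], state.rng)
        event.conditional_transforms = apply_conditional_transitions(state)
        state.record_event(event)
        update_global_parameters(state)
        if check_invariants:
            state.assert_conservation()
        n_events += 1
        if max_events is not None and n_events >= max_events:
            end_reason = "event-cap"
            end_time = state.t
            break

    # censor everything still alive at the end of the recorded span
    for pool in state.living.values():
        for node_id in pool.ids:
            state.forest.close(node_id, end_time, "censored")
    state.forest.end_time = end_time

    return RunResult(
        seed=state.seed,
        events=state.events,
        channel_counts=dict(state.channel_counts),
        times=np.asarray(state.series_times),
        population_series={
            sp: np.asarray(v, dtype=np.int64)
            for sp, v in state.series_counts.items()
        },
        forest=state.forest,
        end_time=end_time,
        end_reason=end_reason,
        rule_names=tuple(state.lhs),
    )


def run_batch(
    program: Program,
    seeds,
    t_span: float | None = None,
    **kwargs,
) -> list[RunResult]:
    """Independent runs, one per seed, in seed order."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seeds must be non-empty")
    if len(set(seeds)) != len(seeds):
        warnings.warn(
            "duplicate seeds produce identical runs", stacklevel=2
        )
    return [run(program, seed=s, t_span=t_span, **kwargs) for s in seeds]
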