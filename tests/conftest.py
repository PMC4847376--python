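"""Shared fixtures: bundled programs, small synthetic programs, heavy runs
computed once per session."""

from __future__ import annotations

import pytest

import estg
from estg.cli import fixture_path


def load_fixture(name: str) -> estg.Program:
    """A freshly parsed and validated bundled program."""
    return estg.validate_program(estg.parse_program(fixture_path(name).read_text()))


def make_program(xml: str) -> estg.Program:
    return estg.validate_program(estg.parse_program(xml))


def pure_birth_xml(rate: float = 0.5, init: int = 50, sim_time: float = 2.0) -> str:
    """Yule process: A divides at a fixed rate, never dies."""
    return f"""
    <Program>
      <ExecParams><SimTime>{sim_time}</SimTime><Seed>1</Seed></ExecParams>
      <Rule>
        <Name>A</Name><InitPop>{init}</InitPop><Rate>{rate}</Rate>
        <Prod><Products>A,A</Products><Prob>1</Prob></Prod>
      </Rule>
    </Program>
    """


def single_death_xml() -> str:
    """One individual, one possible event: its death."""
    return """
    <Program>
      <ExecParams><SimTime>100</SimTime><Seed>1</Seed></ExecParams>
      <Rule>
        <Name>A</Name><InitPop>1</InitPop><Rate>1</Rate>
        <Prod><Products></Products><Prob>1</Prob></Prod>
      </Rule>
    </Program>
    """


def critical_sc_xml(init: int = 20, sim_time: float = 20.0) -> str:
    """Critical branching: SC divides into two SC or two (inert) Diff with
    equal probability; mean |SC| is a martingale."""
    return f"""
    <Program>
      <ExecParams><SimTime>{sim_time}</SimTime><Seed>1</Seed></ExecParams>
      <Rule>
        <Name>SC</Name><InitPop>{init}</InitPop><Rate>0.1</Rate>
        <Prod><Products>SC,SC</Products><Prob>0.5</Prob></Prod>
        <Prod><Products>Diff,Diff</Products><Prob>ow</Prob></Prod>
      </Rule>
      <Rule>
        <Name>Diff</Name><InitPop>0</InitPop><Rate>0</Rate>
        <Prod><Products>Diff,Diff</Products><Prob>1</Prob></Prod>
      </Rule>
    </Program>
    """


def subcritical_diff_xml(init: int = 40, sim_time: float = 10.0) -> str:
    """Slightly subcritical birth-death: divide 0.49 / die 0.51 at rate 1,
    so the mean decays as exp(-0.02 t)."""
    return f"""
    <Program>
      <ExecParams><SimTime>{sim_time}</SimTime><Seed>1</Seed></ExecParams>
      <Rule>
        <Name>Diff</Name><InitPop>{init}</InitPop><Rate>1</Rate>
        <Prod><Products>Diff,Diff</Products><Prob>0.49</Prob></Prod>
        <Prod><Products></Products><Prob>ow</Prob></Prod>
      </Rule>
    </Program>
    """


class ScriptedRNG:
    """Deterministic stand-in for a Generator, fed from preset sequences."""

    def __init__(self, uniforms=(), ints=(), normals=()):
        self._uniforms = list(uniforms)
        self._ints = list(ints)
        self._normals = list(normals)

    def random(self):
        return self._uniforms.pop(0)

    def integers(self, low, high=None):
        return self._ints.pop(0)

    def normal(self, mu, sigma):
        return self._normals.pop(0)


@pytest.fixture(scope="session")
def lv_run():
    """One full Lotka-Volterra execution at the bundled configuration
    (900 prey + 900 predators, 10 time units); shared across tests because
    it is the heaviest single run in the suite."""
    program = load_fixture("lotka_volterra")
    return estg.run(program, seed=1, max_events=2_000_000)


@pytest.fixture(scope="session")
def stem_cell_runs():
    """Replicate runs of the stem-cell differentiation program, enough for
    parameter-recovery checks (>= 20000 firings of each rule)."""
    program = load_fixture("stem_cell_ms")
    runs = []
    sc = diff = 0
    seed = 1
    while sc < 20_000 or diff < 20_000:
        r = estg.run(program, seed=seed)
        counts = r.rule_counts()
        sc += counts["SC"]
        diff += counts["Diff"]
        runs.append(r)
        seed += 1
    return runs


@pytest.fixture(scope="session")
def conditional_toy_runs():
    """Replicate runs of the conditional-transitions toy program with at
    least 10000 recorded stochastic-counter increments."""
    from estg.stats import state_increments

    program = load_fixture("conditional_toy")
    runs = []
    total = 0
    seed = 1
    while total < 10_000:
        r = estg.run(program, seed=seed)
        total += state_increments([r], "CounterStoch").size
        runs.append(r)
        seed += 1
    return runs
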