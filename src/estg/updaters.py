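"""Built-in internal-state and global updating functions.

Internal-state updaters are called at every inheritance event: when a rule
fires (or a conditional transition creates a child that shares the state with
its parent is *not* updated -- carry-over is a plain copy), each child's state
instance is computed from the parent's corresponding instance.  The contract
is ``fn(x, rng) -> new value`` with ``rng`` a :class:`numpy.random.Generator`.

Global updaters rewrite rule rates and outcome probabilities from the system
state after every event.  The contract is
``fn(populations, t, constants) -> {lhs_species: (rate, [probabilities])}``;
rules absent from the returned mapping are left unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MsParams",
    "LvParams",
    "ms_step",
    "make_ms_step",
    "gen_increment",
    "stochastic_counter",
    "make_stochastic_counter",
    "identity",
    "lotka_volterra_updater",
    "lotka_volterra",
    "empty",
]


@dataclass(frozen=True)
class MsParams:
    """Symmetric single-step microsatellite mutation model.

    ``p`` is the probability that a locus changes its repeat count at a
    division (split evenly between +1 and -1).
    """

    p: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"MS change probability must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class LvParams:
    """Lotka-Volterra constants (prey growth c1, coupling c2, predator death c3)."""

    c1: float = 10.0
    c2: float = 0.01
    c3: float = 10.0

    def __post_init__(self):
        if not (self.c1 > 0 and self.c2 > 0 and self.c3 > 0):
            raise ValueError("Lotka-Volterra constants must be positive")


def ms_step(x: float, rng, p: float = 0.01) -> float:
    """Symmetric stepwise mutation of a microsatellite repeat count.

    Returns ``x + 1`` with probability ``p/2``, ``x - 1`` with probability
    ``p/2`` and ``x`` otherwise.  Consumes exactly one uniform draw.
    """
    u = rng.random()
    if u < p / 2.0:
        return x + 1.0
    if u < p:
        return x - 1.0
    return x


def make_ms_step(p: float):
    """A registrable ``ms_step`` variant with a fixed change probability."""
    params = MsParams(p)

    def _step(x: float, rng) -> float:
        return ms_step(x, rng, params.p)

    _step.__name__ = f"ms_step_p{p}"
    return _step


def gen_increment(x: float, rng=None) -> float:
    """Generation counter: exact increment by one. Consumes no randomness."""
    return x + 1.0


def stochastic_counter(x: float, rng, mu: float = 1.0, sigma: float = 0.1) -> float:
    """Stochastic counter step: ``x + N(mu, sigma)``. One normal draw."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return x + rng.normal(mu, sigma)


def make_stochastic_counter(mu: float, sigma: float):
    """A registrable stochastic-counter variant with fixed moments."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")

    def _step(x: float, rng) -> float:
        return x + rng.normal(mu, sigma)

    _step.__name__ = f"stochastic_counter_mu{mu}_sigma{sigma}"
    return _step


def identity(x: float, rng=None) -> float:
    """No-op state updater: children inherit the parent value unchanged."""
    return x


def lotka_volterra_updater(populations, params: LvParams):
    """Environment-dependent rates/probabilities of the predator-prey rules.

    Prey fires at ``r1 = c1 + c2*|Predator|`` and divides with probability
    ``p1 = c1/r1`` (otherwise dies); Predator fires at
    ``r2 = c2*|Prey| + c3`` and divides with probability
    ``p2 = c2*|Prey|/r2`` (otherwise dies).  The channel decomposition
    ``r1*p1 = c1`` and ``r1*(1-p1) = c2*|Predator|`` recovers mass-action
    kinetics of the underlying birth/death reactions.
    """
    prey = populations.get("Prey", 0)
    pred = populations.get("Predator", 0)
    r1 = params.c1 + params.c2 * pred
    p1 = params.c1 / r1
    r2 = params.c2 * prey + params.c3
    p2 = params.c2 * prey / r2
    return {
        "Prey": (r1, [p1, 1.0 - p1]),
        "Predator": (r2, [p2, 1.0 - p2]),
    }


def lotka_volterra(populations, t, constants):
    """Registry wrapper for :func:`lotka_volterra_updater`.

    Constants ``c1``, ``c2``, ``c3`` are read from the run's user-constant
    mapping (defaults 10, 0.01, 10).
    """
    params = LvParams(
        c1=float(constants.get("c1", 10.0)),
        c2=float(constants.get("c2", 0.01)),
        c3=float(constants.get("c3", 10.0)),
    )
    return lotka_volterra_updater(populations, params)


def empty(populations, t, constants):
    """No-op global updater: rates and probabilities are never rewritten."""
    return {}
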