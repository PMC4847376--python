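"""Program definition: types, XML parsing, validation, updater registry.

A program is a set of stochastic rewrite rules, one per species::

    A --r--> {S1}_p1 | {S2}_p2 | ... | {Sn}_pn

where ``r`` is the firing rate, the ``p_i`` sum to one, and each outcome
group holds zero (death), one or two product species.  Species may carry
per-individual internal states with named updating functions, and conditional
transitions that transform or kill an individual when a condition on its
internal states holds.  Rates and probabilities may be rewritten after every
event by a named global updating function of the whole system state.

Programs are written in a small XML dialect (see ``fixtures/program.xsd``)
and validated against an :class:`UpdaterRegistry` of named callables.
"""

from __future__ import annotations

import inspect
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Callable

from .expressions import ExpressionError, ExpressionUpdater, SafeExpression

__all__ = [
    "OW",
    "TERMINATION",
    "ProgramError",
    "ProgramParseError",
    "ProgramSchemaError",
    "ProgramValidationError",
    "OutcomeGroup",
    "TransitionRule",
    "InternalStateDef",
    "ConditionalTransitionDef",
    "ExecParams",
    "Program",
    "UpdaterRegistry",
    "builtin_registry",
    "register_updater",
    "parse_program",
    "resolve_ow",
    "validate_program",
    "serialize_program",
]

#: sentinel probability "otherwise" = 1 - sum of the other probabilities
OW = "ow"
#: conditional-transition target meaning death ("{0}" in the XML dialect)
TERMINATION = None

_PROB_TOL = 1e-12


class ProgramError(Exception):
    """Base class for program definition errors."""


class ProgramParseError(ProgramError):
    """Malformed XML."""


class ProgramSchemaError(ProgramError):
    """Well-formed XML that does not fit the program dialect."""


class ProgramValidationError(ProgramError):
    """Structurally parsed program violating a semantic constraint."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OutcomeGroup:
    """One branch of a rule: product species and its probability.

    ``products`` holds 0 (death), 1 or 2 species names; ``probability`` is a
    number in [0, 1] or the sentinel :data:`OW`.
    """

    products: tuple[str, ...]
    probability: float | str

    def __post_init__(self):
        self.products = tuple(self.products)
        if len(self.products) > 2:
            raise ProgramValidationError(
                f"outcome group {self.products} has more than two products"
            )


@dataclass
class TransitionRule:
    """A species' stochastic rewrite rule."""

    lhs: str
    rate: float
    outcomes: list[OutcomeGroup]
    initial_population: int = 0

    @property
    def probabilities(self) -> list[float | str]:
        return [g.probability for g in self.outcomes]


@dataclass
class InternalStateDef:
    """Per-individual numeric state: name, initial value, updater, dup count.

    ``dup`` independent instances of the state are simulated per individual
    (e.g. a vector of microsatellite loci).
    """

    name: str
    init_value: float
    updater_name: str
    dup: int = 1
    #: resolved updater callable, attached by validation
    updater: Callable | None = field(default=None, compare=False, repr=False)


@dataclass
class ConditionalTransitionDef:
    """Transform (or kill) an individual when its internal states satisfy
    ``condition``; ``target`` is a species name or :data:`TERMINATION`."""

    source_species: str
    condition: str
    target: str | None
    compiled: SafeExpression | None = field(default=None, compare=False, repr=False)


@dataclass
class ExecParams:
    """Execution parameters embedded in the program file."""

    sim_time: float
    seed: int = 1


@dataclass
class Program:
    """A parsed (and possibly validated) collection of rules."""

    rules: list[TransitionRule]
    internal_states: dict[str, list[InternalStateDef]]
    conditionals: list[ConditionalTransitionDef]
    exec_params: ExecParams
    global_updater_name: str = ""
    validated: bool = field(default=False, compare=False)

    @property
    def species(self) -> list[str]:
        """Declared species, in rule order."""
        return [r.lhs for r in self.rules]

    def rule_for(self, species: str) -> TransitionRule:
        for r in self.rules:
            if r.lhs == species:
                return r
        raise KeyError(species)


# ---------------------------------------------------------------------------
# updater registry
# ---------------------------------------------------------------------------

class UpdaterRegistry:
    """Named updating functions resolvable from program files.

    Built-in names (``ms_step``, ``gen_increment``, ``stochastic_counter``,
    ``identity`` as state updaters; ``lotka_volterra``, ``empty`` as global
    updaters) always resolve and cannot be shadowed.
    """

    def __init__(self):
        from . import updaters as _u

        self.state_updaters: dict[str, Callable] = {
            "ms_step": _u.ms_step,
            "gen_increment": _u.gen_increment,
            "stochastic_counter": _u.stochastic_counter,
            "identity": _u.identity,
        }
        self.global_updaters: dict[str, Callable] = {
            "lotka_volterra": _u.lotka_volterra,
            "empty": _u.empty,
        }
        self._builtins = frozenset(self.state_updaters) | frozenset(
            self.global_updaters
        )

    def register(self, name: str, kind: str, fn: Callable) -> "UpdaterRegistry":
        if not name:
            raise ValueError("updater name must be non-empty")
        if kind not in ("state", "global"):
            raise ValueError(f"kind must be 'state' or 'global', got {kind!r}")
        if name in self._builtins:
            raise ValueError(f"{name!r} is a built-in updater and cannot be replaced")
        if not callable(fn):
            raise TypeError(f"updater {name!r} is not callable")
        _check_arity(name, kind, fn)
        if kind == "state":
            self.state_updaters[name] = fn
        else:
            self.global_updaters[name] = fn
        return self

    def resolve_state(self, name: str) -> Callable:
        try:
            return self.state_updaters[name]
        except KeyError:
            raise ProgramValidationError(
                f"unknown internal-state updater {name!r}"
            ) from None

    def resolve_global(self, name: str) -> Callable:
        try:
            return self.global_updaters[name]
        except KeyError:
            raise ProgramValidationError(
                f"unknown global updater {name!r}"
            ) from None


def _check_arity(name: str, kind: str, fn: Callable) -> None:
    """Reject callables that cannot accept the contract's arguments."""
    need = 2 if kind == "state" else 3  # (x, rng) / (populations, t, constants)
    try:
        sig = inspect.signature(fn)
    except (TypeError, ValueError):  # builtins without introspectable signatures
        return
    max_pos = 0
    for p in sig.parameters.values():
        if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD):
            max_pos += 1
        elif p.kind == p.VAR_POSITIONAL:
            max_pos = need
            break
    required = sum(
        1
        for p in sig.parameters.values()
        if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)
        and p.default is p.empty
    )
    if max_pos < need or required > need:
        raise TypeError(
            f"updater {name!r} must accept {need} positional arguments "
            f"({'x, rng' if kind == 'state' else 'populations, t, constants'})"
        )


_DEFAULT_REGISTRY: UpdaterRegistry | None = None


def builtin_registry() -> UpdaterRegistry:
    """The shared default registry (built-ins plus user registrations)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = UpdaterRegistry()
    return _DEFAULT_REGISTRY


def register_updater(
    registry: UpdaterRegistry, name: str, kind: str, contract: Callable
) -> UpdaterRegistry:
    """Register ``contract`` under ``name``; built-in names are immutable."""
    return registry.register(name, kind, contract)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_RULE_CHILDREN = {"Name", "InitPop", "Rate", "Prod", "InternalState",
                  "ConditionalTransition"}
_PROGRAM_CHILDREN = {"ExecParams", "FunHandleName", "Rule"}


def _require(el: ET.Element, tag: str, context: str) -> ET.Element:
    child = el.find(tag)
    if child is None:
        raise ProgramSchemaError(f"missing required element <{tag}> in {context}")
    return child


def _text(el: ET.Element) -> str:
    return (el.text or "").strip()


def _reject_unknown(el: ET.Element, allowed: set[str], context: str) -> None:
    for child in el:
        if child.tag not in allowed:
            raise ProgramSchemaError(
                f"unknown element <{child.tag}> in {context}"
            )


def parse_program(document: str) -> Program:
    """Parse XML program text into an (unvalidated) :class:`Program`.

    The ``ow`` probability sentinel is preserved; call
    :func:`validate_program` to resolve it and bind updaters.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ProgramParseError(
            f"malformed XML at line {line}, column {col}: {exc.msg if hasattr(exc, 'msg') else exc}"
        ) from exc

    if root.tag != "Program":
        raise ProgramSchemaError(f"root element must be <Program>, got <{root.tag}>")
    _reject_unknown(root, _PROGRAM_CHILDREN, "<Program>")

    exec_el = _require(root, "ExecParams", "<Program>")
    _reject_unknown(exec_el, {"SimTime", "Seed"}, "<ExecParams>")
    sim_time_el = _require(exec_el, "SimTime", "<ExecParams>")
    try:
        sim_time = float(_text(sim_time_el))
    except ValueError:
        raise ProgramSchemaError(
            f"<SimTime> must be a number, got {_text(sim_time_el)!r}"
        ) from None
    seed_el = exec_el.find("Seed")
    seed = int(_text(seed_el)) if seed_el is not None and _text(seed_el) else 1

    fun_el = root.find("FunHandleName")
    global_name = _text(fun_el) if fun_el is not None else ""

    rules: list[TransitionRule] = []
    internal_states: dict[str, list[InternalStateDef]] = {}
    conditionals: list[ConditionalTransitionDef] = []
    seen_lhs: set[str] = set()

    for rule_el in root.findall("Rule"):
        _reject_unknown(rule_el, _RULE_CHILDREN, "<Rule>")
        name = _text(_require(rule_el, "Name", "<Rule>"))
        if not name:
            raise ProgramSchemaError("empty <Name> in <Rule>")
        if name in seen_lhs:
            raise ProgramValidationError(
                f"species {name!r} appears on the left side of more than one "
                "rule; each species may carry at most one transition rule"
            )
        seen_lhs.add(name)

        rate_el = _require(rule_el, "Rate", f"rule {name!r}")
        try:
            rate = float(_text(rate_el))
        except ValueError:
            raise ProgramSchemaError(
                f"<Rate> of rule {name!r} must be a number, got {_text(rate_el)!r}"
            ) from None
        init_el = rule_el.find("InitPop")
        init_pop = int(_text(init_el)) if init_el is not None and _text(init_el) else 0

        outcomes: list[OutcomeGroup] = []
        for prod_el in rule_el.findall("Prod"):
            _reject_unknown(prod_el, {"Products", "Prob"}, f"<Prod> of rule {name!r}")
            products_el = _require(prod_el, "Products", f"<Prod> of rule {name!r}")
            raw = _text(products_el)
            products = tuple(s.strip() for s in raw.split(",") if s.strip())
            prob_el = _require(prod_el, "Prob", f"<Prod> of rule {name!r}")
            prob_text = _text(prob_el)
            prob: float | str
            if prob_text == OW:
                prob = OW
            else:
                try:
                    prob = float(prob_text)
                except ValueError:
                    raise ProgramSchemaError(
                        f"<Prob> of rule {name!r} must be a number or 'ow', "
                        f"got {prob_text!r}"
                    ) from None
            outcomes.append(OutcomeGroup(products, prob))
        if not outcomes:
            raise ProgramSchemaError(f"rule {name!r} has no <Prod> outcome groups")

        rules.append(TransitionRule(name, rate, outcomes, init_pop))

        states = []
        for st_el in rule_el.findall("InternalState"):
            _reject_unknown(
                st_el, {"Name", "InitVal", "FuncName", "DupNum"},
                f"<InternalState> of rule {name!r}",
            )
            st_name = _text(_require(st_el, "Name", f"<InternalState> of {name!r}"))
            init_val = float(
                _text(_require(st_el, "InitVal", f"<InternalState> {st_name!r}"))
            )
            func = _text(_require(st_el, "FuncName", f"<InternalState> {st_name!r}"))
            dup_el = st_el.find("DupNum")
            dup = int(_text(dup_el)) if dup_el is not None and _text(dup_el) else 1
            states.append(InternalStateDef(st_name, init_val, func, dup))
        if states:
            internal_states[name] = states

        for ct_el in rule_el.findall("ConditionalTransition"):
            _reject_unknown(
                ct_el, {"Condition", "Transition"},
                f"<ConditionalTransition> of rule {name!r}",
            )
            cond = _text(_require(ct_el, "Condition", f"conditional of {name!r}"))
            target_text = _text(
                _require(ct_el, "Transition", f"conditional of {name!r}")
            )
            target = TERMINATION if target_text == "{0}" else target_text
            conditionals.append(ConditionalTransitionDef(name, cond, target))

    if not rules:
        raise ProgramSchemaError("program declares no <Rule> elements")

    return Program(
        rules=rules,
        internal_states=internal_states,
        conditionals=conditionals,
        exec_params=ExecParams(sim_time=sim_time, seed=seed),
        global_updater_name=global_name,
    )


# ---------------------------------------------------------------------------
# ow resolution and validation
# ---------------------------------------------------------------------------

def resolve_ow(probabilities: list) -> list[float]:
    """Replace the ``ow`` sentinel by one minus the sum of the others.

    With no ``ow`` present the numeric entries must already sum to one.
    """
    n_ow = sum(1 for p in probabilities if p == OW)
    if n_ow > 1:
        raise ProgramValidationError(
            "at most one outcome group may carry the 'ow' sentinel"
        )
    numeric = [float(p) for p in probabilities if p != OW]
    for p in numeric:
        if not 0.0 <= p <= 1.0:
            raise ProgramValidationError(
                f"probability {p} outside [0, 1]"
            )
    total = sum(numeric)
    if n_ow == 1:
        if total > 1.0 + _PROB_TOL:
            raise ProgramValidationError(
                f"probabilities sum to {total} > 1 with 'ow' present"
            )
        rest = max(0.0, 1.0 - total)
        return [rest if p == OW else float(p) for p in probabilities]
    if abs(total - 1.0) > _PROB_TOL:
        raise ProgramValidationError(
            f"probabilities sum to {total}, expected 1 (no 'ow' to absorb the rest)"
        )
    return [float(p) for p in probabilities]


def validate_program(
    program: Program, registry: UpdaterRegistry | None = None
) -> Program:
    """Resolve ``ow``, cross-check names, bind updaters. Idempotent.

    Returns the same :class:`Program` instance with probabilities resolved,
    each :class:`InternalStateDef` bound to its updater callable and each
    conditional's condition compiled.
    """
    registry = registry or builtin_registry()
    declared = set()
    for rule in program.rules:
        if rule.lhs in declared:
            raise ProgramValidationError(
                f"species {rule.lhs!r} appears on the left side of more than "
                "one rule; each species may carry at most one transition rule"
            )
        declared.add(rule.lhs)

    if program.exec_params.sim_time <= 0:
        raise ProgramValidationError(
            f"simulation time must be positive, got {program.exec_params.sim_time}"
        )

    for rule in program.rules:
        if rule.rate < 0:
            raise ProgramValidationError(
                f"rule {rule.lhs!r} has negative rate {rule.rate}"
            )
        if rule.initial_population < 0:
            raise ProgramValidationError(
                f"rule {rule.lhs!r} has negative initial population"
            )
        for group in rule.outcomes:
            if len(group.products) > 2:
                raise ProgramValidationError(
                    f"outcome {group.products} of rule {rule.lhs!r} has more "
                    "than two products"
                )
            for sp in group.products:
                if sp not in declared:
                    raise ProgramValidationError(
                        f"outcome of rule {rule.lhs!r} names undeclared "
                        f"species {sp!r}"
                    )
        resolved = resolve_ow(rule.probabilities)
        for group, p in zip(rule.outcomes, resolved):
            group.probability = p

    # internal states: bind updaters; shared names must agree on dup so that
    # values can be inherited across species boundaries
    dup_by_name: dict[str, int] = {}
    for species, defs in program.internal_states.items():
        if species not in declared:
            raise ProgramValidationError(
                f"internal states defined for undeclared species {species!r}"
            )
        seen = set()
        for ist in defs:
            if ist.name in seen:
                raise ProgramValidationError(
                    f"duplicate internal state {ist.name!r} on species "
                    f"{species!r}"
                )
            seen.add(ist.name)
            if ist.dup < 1:
                raise ProgramValidationError(
                    f"duplication number of state {ist.name!r} must be >= 1"
                )
            if ist.name in dup_by_name and dup_by_name[ist.name] != ist.dup:
                raise ProgramValidationError(
                    f"internal state {ist.name!r} has differing duplication "
                    "numbers across species; shared states must agree so "
                    "values can be inherited"
                )
            dup_by_name[ist.name] = ist.dup
            ist.updater = _resolve_state_updater(ist.updater_name, registry)

    for cond in program.conditionals:
        if cond.source_species not in declared:
            raise ProgramValidationError(
                f"conditional transition on undeclared species "
                f"{cond.source_species!r}"
            )
        if cond.target is not TERMINATION and cond.target not in declared:
            raise ProgramValidationError(
                f"conditional transition of {cond.source_species!r} targets "
                f"undeclared species {cond.target!r}"
            )
        try:
            cond.compiled = SafeExpression(cond.condition)
        except ExpressionError as exc:
            raise ProgramValidationError(str(exc)) from exc
        state_names = {
            ist.name for ist in program.internal_states.get(cond.source_species, [])
        }
        unknown = cond.compiled.names - state_names
        if unknown:
            raise ProgramValidationError(
                f"condition {cond.condition!r} of species "
                f"{cond.source_species!r} references names not defined as its "
                f"internal states: {sorted(unknown)}"
            )

    if program.global_updater_name:
        registry.resolve_global(program.global_updater_name)

    program.validated = True
    return program


def _resolve_state_updater(name: str, registry: UpdaterRegistry):
    """Bare identifiers resolve in the registry; anything else is compiled
    as an expression over ``x`` in the safe dialect."""
    if name.isidentifier():
        return registry.resolve_state(name)
    try:
        expr = SafeExpression(name)
    except ExpressionError as exc:
        raise ProgramValidationError(
            f"internal-state updater {name!r} is neither a registered name "
            f"nor a valid expression: {exc}"
        ) from exc
    bad = expr.names - {"x"}
    if bad:
        raise ProgramValidationError(
            f"updater expression {name!r} may only reference 'x', found "
            f"{sorted(bad)}"
        )
    return ExpressionUpdater(expr)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _num(x: float) -> str:
    """Shortest exact decimal for a float (round-trips via float())."""
    return repr(float(x))


def serialize_program(program: Program) -> str:
    """Render a program back to XML text.

    ``parse_program(serialize_program(validate_program(p)))`` equals
    ``validate_program(p)`` up to the (non-compared) binding fields.
    """
    root = ET.Element("Program")
    exec_el = ET.SubElement(root, "ExecParams")
    ET.SubElement(exec_el, "SimTime").text = _num(program.exec_params.sim_time)
    ET.SubElement(exec_el, "Seed").text = str(program.exec_params.seed)
    fun_el = ET.SubElement(root, "FunHandleName")
    fun_el.text = program.global_updater_name or ""

    conds_by_species: dict[str, list[ConditionalTransitionDef]] = {}
    for c in program.conditionals:
        conds_by_species.setdefault(c.source_species, []).append(c)

    for rule in program.rules:
        rule_el = ET.SubElement(root, "Rule")
        ET.SubElement(rule_el, "Name").text = rule.lhs
        ET.SubElement(rule_el, "InitPop").text = str(rule.initial_population)
        ET.SubElement(rule_el, "Rate").text = _num(rule.rate)
        for group in rule.outcomes:
            prod_el = ET.SubElement(rule_el, "Prod")
            ET.SubElement(prod_el, "Products").text = ",".join(group.products)
            prob = group.probability
            ET.SubElement(prod_el, "Prob").text = (
                OW if prob == OW else _num(prob)
            )
        for ist in program.internal_states.get(rule.lhs, []):
            st_el = ET.SubElement(rule_el, "InternalState")
            ET.SubElement(st_el, "Name").text = ist.name
            ET.SubElement(st_el, "InitVal").text = _num(ist.init_value)
            ET.SubElement(st_el, "FuncName").text = ist.updater_name
            ET.SubElement(st_el, "DupNum").text = str(ist.dup)
        for cond in conds_by_species.get(rule.lhs, []):
            ct_el = ET.SubElement(rule_el, "ConditionalTransition")
            ET.SubElement(ct_el, "Condition").text = cond.condition
            ET.SubElement(ct_el, "Transition").text = (
                "{0}" if cond.target is TERMINATION else cond.target
            )

    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"
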