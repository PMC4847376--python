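"""Safe expression dialect for program files.

Conditional-transition conditions and inline internal-state updaters in XML
programs are plain text.  They are compiled here against a small whitelist of
Python expression syntax -- arithmetic, comparisons, boolean logic, a handful
of math functions, ``normrnd(mu, sigma)``, ``pop("Species")`` and ``time()``
-- so that loading a program never executes arbitrary code.
"""

from __future__ import annotations

import ast
import math

__all__ = ["ExpressionError", "SafeExpression", "ExpressionUpdater"]


class ExpressionError(ValueError):
    """Raised when an expression does not fit the dialect."""


#: callables addressable from expressions; ``normrnd``/``pop``/``time`` are
#: supplied by the evaluation environment, the rest are bound here.
_ENV_FUNCS = {"normrnd", "pop", "time"}
_SAFE_FUNCS = {
    "abs": abs,
    "min": min,
    "max": max,
    "floor": math.floor,
    "ceil": math.ceil,
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
}
_ALLOWED_CALLS = _ENV_FUNCS | set(_SAFE_FUNCS)

_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp, ast.And, ast.Or,
    ast.UnaryOp, ast.Not, ast.USub, ast.UAdd,
    ast.BinOp, ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.Mod,
    ast.FloorDiv,
    ast.Compare, ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt, ast.GtE,
    ast.Call, ast.Name, ast.Load, ast.Constant, ast.Subscript, ast.IfExp,
    ast.Tuple,
)


class SafeExpression:
    """A compiled, whitelisted arithmetic/boolean expression.

    Parameters
    ----------
    text:
        Expression source, e.g. ``"CounterStoch > 5"`` or
        ``"x + normrnd(1, 0.1)"``.

    Attributes
    ----------
    names:
        Frozenset of bare identifiers the expression reads (function names
        excluded); used at validation time to cross-check that conditions
        reference only internal states defined on their species.
    """

    __slots__ = ("text", "names", "dynamic", "_code")

    def __init__(self, text: str):
        self.text = text.strip()
        if not self.text:
            raise ExpressionError("empty expression")
        try:
            tree = ast.parse(self.text, mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(
                f"invalid expression {self.text!r}: {exc.msg}"
            ) from exc

        func_names: set[str] = set()
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_NODES):
                raise ExpressionError(
                    f"{type(node).__name__} not allowed in expression "
                    f"{self.text!r}"
                )
            if isinstance(node, ast.Call):
                if not isinstance(node.func, ast.Name):
                    raise ExpressionError(
                        f"only named function calls allowed in {self.text!r}"
                    )
                if node.func.id not in _ALLOWED_CALLS:
                    raise ExpressionError(
                        f"function {node.func.id!r} not allowed in "
                        f"{self.text!r}"
                    )
                if node.keywords:
                    raise ExpressionError(
                        f"keyword arguments not allowed in {self.text!r}"
                    )
                func_names.add(node.func.id)
            if isinstance(node, ast.Constant) and not isinstance(
                node.value, (int, float, bool, str)
            ):
                raise ExpressionError(
                    f"constant {node.value!r} not allowed in {self.text!r}"
                )
            if isinstance(node, ast.Subscript) and not (
                isinstance(node.slice, ast.Constant)
                and isinstance(node.slice.value, int)
            ):
                raise ExpressionError(
                    f"only constant integer indices allowed in {self.text!r}"
                )

        self.names = frozenset(
            n.id
            for n in ast.walk(tree)
            if isinstance(n, ast.Name) and n.id not in func_names
        )
        #: True when the value can change between evaluations for the same
        #: individual (environment access or randomness); such conditions
        #: must be re-examined at every event rather than once per node
        self.dynamic = bool(func_names & _ENV_FUNCS)
        self._code = compile(tree, "<estg-expr>", "eval")

    def evaluate(self, env: dict):
        """Evaluate with ``env`` providing identifiers and env functions."""
        scope = dict(_SAFE_FUNCS)
        scope.update(env)
        return eval(self._code, {"__builtins__": {}}, scope)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SafeExpression({self.text!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, SafeExpression) and self.text == other.text

    def __hash__(self) -> int:
        return hash(self.text)


class ExpressionUpdater:
    """Internal-state updater defined by an expression over ``x``.

    Bound from XML when ``FuncName`` is not a bare registry identifier.  The
    engine calls it as ``fn(x, rng, env)`` (``needs_env`` marks the extended
    signature); ``normrnd`` draws come from the run's random stream.
    """

    needs_env = True
    __slots__ = ("expression",)

    def __init__(self, expression: SafeExpression):
        self.expression = expression

    def __call__(self, x: float, rng, env: dict | None = None) -> float:
        scope = {"x": x, "normrnd": lambda mu, sigma: rng.normal(mu, sigma)}
        if env:
            scope.update(env)
        return self.expression.evaluate(scope)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionUpdater({self.expression.text!r})"
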