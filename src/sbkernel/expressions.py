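"""Kinetic-law and trigger mathematics.

Expressions are sympy trees restricted to a practical core: arithmetic,
``exp``/``ln``/``log10``, ``min``/``max``/``abs``, piecewise, comparisons and
boolean connectives, numeric literals and plain symbols.  Everything a model
can state — kinetic laws, rule right-hand sides, event triggers, constraint
conditions — lives in this grammar, and the parser binds *every* identifier to
a fresh :class:`sympy.Symbol` so that species named ``E``, ``I`` or ``N`` never
collide with sympy's built-in constants.
"""

from __future__ import annotations

import re
from typing import Mapping, Union

import sympy as sp
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

Expression = Union[sp.Expr, sp.logic.boolalg.Boolean]

__all__ = [
    "Expression",
    "ExpressionError",
    "EvaluationError",
    "SymbolResolutionError",
    "parse_expression",
    "format_expression",
    "evaluate",
    "free_symbols",
    "boolean_to_numeric",
    "is_boolean_expression",
]


class ExpressionError(ValueError):
    """Base class for expression problems."""


class SymbolResolutionError(ExpressionError):
    """A free symbol is not bound in the evaluation environment."""


class EvaluationError(ExpressionError):
    """Evaluation hit an undefined value (division by zero, log of <=0, ...).

    Carries the offending subexpression as ``subexpression``.
    """

    def __init__(self, message: str, subexpression=None):
        super().__init__(message)
        self.subexpression = subexpression


def _piecewise(*args):
    """``piecewise(v1, c1, v2, c2, ..., [default])`` -> sympy Piecewise.

    The first true condition wins; a trailing unpaired value is the default.
    Also accepts sympy's native pair form ``piecewise((v1, c1), (v2, c2))``.
    """
    if args and all(isinstance(a, tuple) for a in args):
        return sp.Piecewise(*args)
    pairs = []
    n = len(args)
    i = 0
    while i + 1 < n:
        pairs.append((args[i], args[i + 1]))
        i += 2
    if i < n:  # trailing default value
        pairs.append((args[i], sp.true))
    if not pairs:
        raise ExpressionError("piecewise() needs at least one argument")
    return sp.Piecewise(*pairs)


_FUNCTIONS = {
    "exp": sp.exp,
    "ln": sp.log,
    "log": sp.log,
    "log10": lambda x: sp.log(x, 10),
    "pow": sp.Pow,
    "sqrt": sp.sqrt,
    "min": sp.Min,
    "max": sp.Max,
    "abs": sp.Abs,
    "piecewise": _piecewise,
    "floor": sp.floor,
    "ceil": sp.ceiling,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "true": sp.true,
    "false": sp.false,
}

# names parse_expr needs for literals
_GLOBALS = {
    "Symbol": sp.Symbol,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    **_FUNCTIONS,
}

_IDENT = re.compile(r"[A-Za-z_][A-Za-z_0-9]*")


def parse_expression(text: str) -> Expression:
    """Parse an expression string into a sympy tree.

    Every identifier that is not a known function name becomes a Symbol.
    ``^`` is accepted as power.  Raises :class:`ExpressionError` on syntax
    errors or unsupported constructs.
    """
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError("empty expression")
    src = text.replace("^", "**")
    local = {}
    for name in _IDENT.findall(src):
        if name.lower() in _FUNCTIONS:
            continue
        local[name] = sp.Symbol(name)
    # case-normalize function names (MathML and users write Min/ABS etc.)
    def repl(m):
        name = m.group(0)
        return name.lower() if name.lower() in _FUNCTIONS else name

    src = _IDENT.sub(repl, src)
    try:
        expr = parse_expr(
            src,
            local_dict=local,
            global_dict=_GLOBALS,
            transformations=standard_transformations,
            evaluate=True,
        )
    except Exception as exc:  # sympy raises a zoo of exception types
        raise ExpressionError(f"cannot parse expression {text!r}: {exc}") from exc
    return expr


_PRINTER = sp.StrPrinter(settings={"order": "lex"})


def format_expression(expr: Expression) -> str:
    """Deterministic textual form, re-parsable by :func:`parse_expression`."""
    return _PRINTER.doprint(expr)


def free_symbols(expr: Expression) -> set[str]:
    return {s.name for s in expr.free_symbols}


def evaluate(expr: Expression, env: Mapping[str, float]):
    """Evaluate ``expr`` with every free symbol bound in ``env``.

    Returns a float for numeric expressions and a bool for boolean ones.
    Piecewise picks the first branch whose condition is true.
    """
    missing = free_symbols(expr) - set(env)
    if missing:
        raise SymbolResolutionError(
            f"unbound symbol(s) {sorted(missing)} in {format_expression(expr)}"
        )
    subs = {sp.Symbol(k): sp.Float(v) for k, v in env.items() if isinstance(v, (int, float))}
    result = expr.xreplace(subs)
    if isinstance(result, sp.logic.boolalg.Boolean) and result in (sp.true, sp.false):
        return bool(result)
    result = sp.simplify(result) if not result.is_number else result
    if result in (sp.true, sp.false):
        return bool(result)
    if not result.is_number:
        raise EvaluationError(
            f"expression did not reduce to a number: {format_expression(result)}",
            subexpression=result,
        )
    value = complex(result)
    if value.imag != 0.0:
        raise EvaluationError(
            f"complex value from {format_expression(expr)} (log of a nonpositive number?)",
            subexpression=expr,
        )
    real = value.real
    if not _finite(real):
        raise EvaluationError(
            f"non-finite value from {format_expression(expr)} (division by zero?)",
            subexpression=expr,
        )
    return real


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def is_boolean_expression(expr: Expression) -> bool:
    return isinstance(expr, sp.logic.boolalg.Boolean) or isinstance(
        expr, sp.core.relational.Relational
    )


def boolean_to_numeric(expr: Expression) -> sp.Expr:
    """Encode a boolean expression as a 0/1 numeric expression.

    Comparisons become indicator piecewises, conjunction a product,
    disjunction a saturating sum and negation ``1 - x``; on every
    environment the numeric form equals 1 exactly when the boolean form is
    true.  Numeric expressions pass through with any embedded boolean
    subtrees (piecewise conditions) left intact.
    """
    if expr is sp.true or expr is True:
        return sp.Integer(1)
    if expr is sp.false or expr is False:
        return sp.Integer(0)
    if isinstance(expr, sp.core.relational.Relational):
        return sp.Piecewise((1, expr), (0, True))
    if isinstance(expr, sp.And):
        out = sp.Integer(1)
        for a in expr.args:
            out = out * boolean_to_numeric(a)
        return out
    if isinstance(expr, sp.Or):
        total = sp.Integer(0)
        for a in expr.args:
            total = total + boolean_to_numeric(a)
        return sp.Min(sp.Integer(1), total)
    if isinstance(expr, sp.Not):
        return sp.Integer(1) - boolean_to_numeric(expr.args[0])
    if isinstance(expr, sp.Symbol) or expr.is_number:
        return expr
    return expr
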