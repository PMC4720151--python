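"""Boolean rule expressions.

Rules are stored as explicit expression trees (not truth tables) so that the
same object can be evaluated with strict Boolean semantics, vectorized over
bit-parallel state arrays, or fuzzified into the min/max/(1-x) algebra used
by the continuous engine.

Text syntax (BoolNet style): identifiers, ``&`` (AND), ``|`` (OR), ``!``
(NOT) and parentheses; ``!`` binds tightest, then ``&``, then ``|``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "BoolExpr",
    "Var",
    "Not",
    "And",
    "Or",
    "FuzzyExpr",
    "parse_expression",
    "ExpressionError",
]


class ExpressionError(ValueError):
    """Raised for syntactically invalid rule expressions."""


class BoolExpr:
    """Base class for rule expression trees. Immutable and hashable."""

    def eval(self, env: Mapping[str, int]) -> int:
        """Strict Boolean evaluation over a total {0,1} assignment."""
        raise NotImplementedError

    def eval_bits(self, env: Mapping[str, np.ndarray]) -> np.ndarray:
        """Vectorized evaluation over boolean numpy arrays (bit-parallel)."""
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        return frozenset(name for name, _ in self.literals())

    def literals(self) -> Iterator[tuple[str, bool]]:
        """Yield (variable, negated) for every literal occurrence, in order."""
        raise NotImplementedError

    def to_fuzzy(self) -> "FuzzyExpr":
        """Structure-preserving fuzzification: AND->min, OR->max, NOT->1-x."""
        return FuzzyExpr(self)

    def to_text(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.to_text()


@dataclass(frozen=True)
class Var(BoolExpr):
    name: str

    def eval(self, env):
        return 1 if env[self.name] else 0

    def eval_bits(self, env):
        return env[self.name]

    def eval_fuzzy(self, env):
        return env[self.name]

    def literals(self):
        yield (self.name, False)

    def to_text(self):
        return self.name


@dataclass(frozen=True)
class Not(BoolExpr):
    arg: BoolExpr

    def eval(self, env):
        return 1 - self.arg.eval(env)

    def eval_bits(self, env):
        return ~self.arg.eval_bits(env)

    def eval_fuzzy(self, env):
        return 1.0 - self.arg.eval_fuzzy(env)

    def literals(self):
        for name, neg in self.arg.literals():
            yield (name, not neg)

    def to_text(self):
        inner = self.arg.to_text()
        if isinstance(self.arg, (And, Or)):
            return f"!({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And(BoolExpr):
    args: tuple[BoolExpr, ...]

    def __init__(self, *args: BoolExpr):
        if len(args) < 2:
            raise ExpressionError("AND requires at least two operands")
        # canonical flat form: nested ANDs are associatively merged
        flat: list[BoolExpr] = []
        for a in args:
            flat.extend(a.args if isinstance(a, And) else (a,))
        object.__setattr__(self, "args", tuple(flat))

    def eval(self, env):
        return int(all(a.eval(env) for a in self.args))

    def eval_bits(self, env):
        out = self.args[0].eval_bits(env)
        for a in self.args[1:]:
            out = out & a.eval_bits(env)
        return out

    def eval_fuzzy(self, env):
        out = self.args[0].eval_fuzzy(env)
        for a in self.args[1:]:
            out = np.minimum(out, a.eval_fuzzy(env))
        return out

    def literals(self):
        for a in self.args:
            yield from a.literals()

    def to_text(self):
        parts = [
            f"({a.to_text()})" if isinstance(a, Or) else a.to_text()
            for a in self.args
        ]
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(BoolExpr):
    args: tuple[BoolExpr, ...]

    def __init__(self, *args: BoolExpr):
        if len(args) < 2:
            raise ExpressionError("OR requires at least two operands")
        # canonical flat form: nested ORs are associatively merged
        flat: list[BoolExpr] = []
        for a in args:
            flat.extend(a.args if isinstance(a, Or) else (a,))
        object.__setattr__(self, "args", tuple(flat))

    def eval(self, env):
        return int(any(a.eval(env) for a in self.args))

    def eval_bits(self, env):
        out = self.args[0].eval_bits(env)
        for a in self.args[1:]:
            out = out | a.eval_bits(env)
        return out

    def eval_fuzzy(self, env):
        out = self.args[0].eval_fuzzy(env)
        for a in self.args[1:]:
            out = np.maximum(out, a.eval_fuzzy(env))
        return out

    def literals(self):
        for a in self.args:
            yield from a.literals()

    def to_text(self):
        return " | ".join(a.to_text() for a in self.args)


class FuzzyExpr:
    """Fuzzy-logic view of a Boolean expression tree.

    Evaluates the same tree with AND -> min, OR -> max, NOT -> 1-x over
    activation levels in [0,1] (scalars or numpy arrays). Restricted to
    {0,1} inputs it coincides with the Boolean semantics.
    """

    def __init__(self, tree: BoolExpr):
        self.tree = tree

    def eval(self, env: Mapping[str, float]) -> float:
        return self.tree.eval_fuzzy(env)

    def variables(self) -> frozenset[str]:
        return self.tree.variables()

    def to_text(self) -> str:
        return _fuzzy_text(self.tree)

    def __str__(self) -> str:  # pragma: no cover
        return self.to_text()


def _fuzzy_text(tree: BoolExpr) -> str:
    if isinstance(tree, Var):
        return tree.name
    if isinstance(tree, Not):
        return f"(1 - {_fuzzy_text(tree.arg)})"
    if isinstance(tree, And):
        return "min(" + ", ".join(_fuzzy_text(a) for a in tree.args) + ")"
    if isinstance(tree, Or):
        return "max(" + ", ".join(_fuzzy_text(a) for a in tree.args) + ")"
    raise TypeError(tree)


_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.-]*)|(?P<op>[&|!()]))")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ExpressionError(
                    f"unexpected character {text[pos:].strip()[0]!r} in expression {text!r}"
                )
            break
        tokens.append(m.group("name") or m.group("op"))
        pos = m.end()
    return tokens


def parse_expression(text: str) -> BoolExpr:
    """Parse a rule expression with precedence ``!`` > ``&`` > ``|``."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_or() -> BoolExpr:
        terms = [parse_and()]
        while peek() == "|":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def parse_and() -> BoolExpr:
        factors = [parse_not()]
        while peek() == "&":
            take()
            factors.append(parse_not())
        return factors[0] if len(factors) == 1 else And(*factors)

    def parse_not() -> BoolExpr:
        if peek() == "!":
            take()
            return Not(parse_not())
        return parse_atom()

    def parse_atom() -> BoolExpr:
        tok = take()
        if tok == "(":
            inner = parse_or()
            if take() != ")":
                raise ExpressionError(f"unbalanced parentheses in {text!r}")
            return inner
        if tok is None or tok in "&|!)":
            raise ExpressionError(f"unexpected token {tok!r} in {text!r}")
        return Var(tok)

    tree = parse_or()
    if pos != len(tokens):
        raise ExpressionError(f"trailing tokens {tokens[pos:]} in {text!r}")
    return tree
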