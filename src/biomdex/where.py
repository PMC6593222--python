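"""Typed where-clause language over sample-metadata variables.

Grammar (by example): ``empo_3=='Soil (non-saline)' and ph > 0``,
``ph < 7 or (country in ('USA', 'Peru') and depth >= 10)``.

Comparisons are ``variable OP literal`` with OP one of ``== != < <= > >=
in notin``; literals are single- or double-quoted strings, numbers, or
parenthesised/bracketed lists for ``in``/``notin``.  Comparisons combine
with ``and`` / ``or`` (and binds tighter) and parentheses.

Values are stored as raw strings and typed at query time: ordering
operators coerce the stored value to a number and simply exclude a sample
whose value is missing or non-coercible, so ``ph > 0`` doubles as a
has-valid-pH filter.  Equality compares exact strings unless both sides
coerce numerically, in which case numeric equality is used (``ph == 7``
matches a stored ``"7.0"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union


class WhereSyntaxError(ValueError):
    """Malformed clause; carries the character position of the problem."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class WhereEvaluationError(ValueError):
    """Clause is well-formed but cannot be evaluated as written."""


_COMPARISON_OPS = ("==", "!=", "<=", ">=", "<", ">", "in", "notin")
_ORDERING_OPS = frozenset({"<", "<=", ">", ">="})


@dataclass(frozen=True)
class Comparison:
    variable: str
    op: str
    literal: Union[str, float, tuple]

    def __post_init__(self):
        if self.op not in _COMPARISON_OPS:
            raise WhereEvaluationError(f"unknown operator {self.op!r}")


@dataclass(frozen=True)
class And:
    left: "Clause"
    right: "Clause"


@dataclass(frozen=True)
class Or:
    left: "Clause"
    right: "Clause"


Clause = Union[Comparison, And, Or]


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_PUNCT = {"==", "!=", "<=", ">=", "<", ">", "(", ")", ",", "[", "]", "{", "}"}


def _tokenize(text: str) -> list[tuple[str, object, int]]:
    """Return (kind, value, position) triples.

    Kinds: ``ident``, ``number``, ``string``, ``punct``, ``keyword``.
    """
    tokens: list[tuple[str, object, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "'\"":
            j = text.find(c, i + 1)
            if j < 0:
                raise WhereSyntaxError("unterminated string literal", i)
            tokens.append(("string", text[i + 1:j], i))
            i = j + 1
            continue
        two = text[i:i + 2]
        if two in _PUNCT:
            tokens.append(("punct", two, i))
            i += 2
            continue
        if c in _PUNCT:
            tokens.append(("punct", c, i))
            i += 1
            continue
        if c.isdigit() or (c in "+-." and i + 1 < n
                           and (text[i + 1].isdigit() or text[i + 1] == ".")):
            j = i + 1
            while j < n and (text[j].isalnum() or text[j] in ".+-"):
                # permit scientific notation; validated by float() below
                if text[j] in "+-" and text[j - 1] not in "eE":
                    break
                j += 1
            try:
                value = float(text[i:j])
            except ValueError:
                raise WhereSyntaxError(
                    f"malformed number {text[i:j]!r}", i) from None
            tokens.append(("number", value, i))
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i + 1
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            word = text[i:j]
            if word.lower() in ("and", "or", "in", "notin"):
                tokens.append(("keyword", word.lower(), i))
            else:
                tokens.append(("ident", word, i))
            i = j
            continue
        raise WhereSyntaxError(f"unexpected character {c!r}", i)
    return tokens


# ---------------------------------------------------------------------------
# recursive-descent parser: or_expr > and_expr > atom
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise WhereSyntaxError("unexpected end of clause", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> Clause:
        clause = self._or_expr()
        trailing = self._peek()
        if trailing is not None:
            raise WhereSyntaxError(
                f"unexpected trailing {trailing[1]!r}", trailing[2])
        return clause

    def _or_expr(self) -> Clause:
        node = self._and_expr()
        while True:
            tok = self._peek()
            if tok and tok[0] == "keyword" and tok[1] == "or":
                self._next()
                node = Or(node, self._and_expr())
            else:
                return node

    def _and_expr(self) -> Clause:
        node = self._atom()
        while True:
            tok = self._peek()
            if tok and tok[0] == "keyword" and tok[1] == "and":
                self._next()
                node = And(node, self._atom())
            else:
                return node

    def _atom(self) -> Clause:
        kind, value, pos = self._next()
        if kind == "punct" and value == "(":
            node = self._or_expr()
            kind, value, pos = self._next()
            if not (kind == "punct" and value == ")"):
                raise WhereSyntaxError("expected ')'", pos)
            return node
        if kind != "ident":
            raise WhereSyntaxError(
                f"expected a variable name, got {value!r}", pos)
        variable = value
        kind, op, pos = self._next()
        if kind == "keyword" and op in ("in", "notin"):
            return Comparison(variable, op, self._set_literal())
        if kind == "punct" and op in ("==", "!=", "<", "<=", ">", ">="):
            return Comparison(variable, op, self._scalar_literal())
        raise WhereSyntaxError(f"expected a comparison operator, got "
                               f"{op!r}", pos)

    def _scalar_literal(self):
        kind, value, pos = self._next()
        if kind in ("string", "number"):
            return value
        raise WhereSyntaxError(
            f"expected a string or number literal, got {value!r}", pos)

    def _set_literal(self) -> tuple:
        kind, value, pos = self._next()
        closers = {"(": ")", "[": "]", "{": "}"}
        if not (kind == "punct" and value in closers):
            raise WhereSyntaxError("expected a literal list after in/notin",
                                   pos)
        closer = closers[value]
        items = []
        while True:
            kind, value, pos = self._next()
            if kind == "punct" and value == closer and not items:
                break  # empty set permitted
            if kind not in ("string", "number"):
                raise WhereSyntaxError(
                    f"expected a string or number in list, got {value!r}",
                    pos)
            items.append(value)
            kind, value, pos = self._next()
            if kind == "punct" and value == closer:
                break
            if not (kind == "punct" and value == ","):
                raise WhereSyntaxError("expected ',' or closing bracket", pos)
        return tuple(items)


def parse_where(clause: str | Clause) -> Clause:
    """Parse clause text into an expression tree (idempotent on trees)."""
    if isinstance(clause, (Comparison, And, Or)):
        return clause
    return _Parser(clause).parse()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _coerce(value) -> float | None:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _equal(stored: str, literal) -> bool:
    stored_num = _coerce(stored)
    literal_num = literal if isinstance(literal, float) else _coerce(literal)
    if stored_num is not None and literal_num is not None:
        return stored_num == literal_num
    return stored == (literal if isinstance(literal, str) else str(literal))


def evaluate_comparison(value: str | None, comp: Comparison) -> bool:
    """Evaluate one comparison against a sample's raw stored value.

    A missing value never satisfies any comparison, including ``!=`` and
    ``notin``: absence is treated as unknown, not as difference.
    """
    if value is None:
        return False
    op = comp.op
    if op in _ORDERING_OPS:
        stored = _coerce(value)
        if stored is None:
            return False
        bound = comp.literal if isinstance(comp.literal, float) \
            else _coerce(comp.literal)
        if bound is None:
            raise WhereEvaluationError(
                f"ordering comparison on {comp.variable!r} needs a numeric "
                f"literal, got {comp.literal!r}")
        return {"<": stored < bound, "<=": stored <= bound,
                ">": stored > bound, ">=": stored >= bound}[op]
    if op == "==":
        return _equal(value, comp.literal)
    if op == "!=":
        return not _equal(value, comp.literal)
    if op == "in":
        return any(_equal(value, item) for item in comp.literal)
    if op == "notin":
        return not any(_equal(value, item) for item in comp.literal)
    raise WhereEvaluationError(f"unknown operator {op!r}")


def clause_variables(clause: Clause) -> set[str]:
    if isinstance(clause, Comparison):
        return {clause.variable}
    return clause_variables(clause.left) | clause_variables(clause.right)


def evaluate_clause(clause: Clause, values: dict[str, str | None]) -> bool:
    """Evaluate a parsed clause against one sample's variable->value map."""
    if isinstance(clause, Comparison):
        return evaluate_comparison(values.get(clause.variable), clause)
    if isinstance(clause, And):
        return (evaluate_clause(clause.left, values)
                and evaluate_clause(clause.right, values))
    if isinstance(clause, Or):
        return (evaluate_clause(clause.left, values)
                or evaluate_clause(clause.right, values))
    raise WhereEvaluationError(f"not a clause node: {clause!r}")
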