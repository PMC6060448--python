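"""Boolean expression trees for transition functions.

Expressions are immutable nested tuples::

    ("const", 0|1)
    ("var", name)
    ("not", expr)
    ("and", expr, expr, ...)
    ("or", expr, expr, ...)

The rule dialect uses ``!`` (negation), ``&`` (conjunction), ``|``
(disjunction), parentheses, the literals ``0``/``1`` and node names made of
letters, digits and underscores.  ``&`` binds tighter than ``|``; ``!`` binds
tightest.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping

Expr = tuple

TRUE: Expr = ("const", 1)
FALSE: Expr = ("const", 0)


class ExprSyntaxError(ValueError):
    """Raised on malformed rule text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# parsing

_NAME_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "!&|()":
            tokens.append((c, c, i))
            i += 1
        elif c in _NAME_CHARS:
            j = i
            while j < n and text[j] in _NAME_CHARS:
                j += 1
            word = text[i:j]
            if word in ("0", "1"):
                tokens.append(("const", word, i))
            elif word[0].isdigit():
                raise ExprSyntaxError(f"invalid name {word!r}", i)
            else:
                tokens.append(("name", word, i))
            i = j
        else:
            raise ExprSyntaxError(f"unexpected character {c!r}", i)
    return tokens


def parse_expression(text: str) -> Expr:
    """Parse one rule expression into an expression tree."""
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None, len(text))

    def take(kind):
        nonlocal pos
        tok = peek()
        if tok[0] != kind:
            raise ExprSyntaxError(f"expected {kind!r}, found {tok[1]!r}", tok[2])
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek()[0] == "|":
            take("|")
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", *terms)

    def parse_and():
        factors = [parse_unary()]
        while peek()[0] == "&":
            take("&")
            factors.append(parse_unary())
        return factors[0] if len(factors) == 1 else ("and", *factors)

    def parse_unary():
        kind, value, at = peek()
        if kind == "!":
            take("!")
            return ("not", parse_unary())
        if kind == "(":
            take("(")
            inner = parse_or()
            take(")")
            return inner
        if kind == "const":
            take("const")
            return ("const", int(value))
        if kind == "name":
            take("name")
            return ("var", value)
        raise ExprSyntaxError(f"unexpected token {value!r}", at)

    expr = parse_or()
    if pos != len(tokens):
        kind, value, at = tokens[pos]
        raise ExprSyntaxError(f"trailing token {value!r}", at)
    return expr


# ---------------------------------------------------------------------------
# inspection / evaluation

def support(expr: Expr) -> frozenset[str]:
    """Names of all variables referenced by *expr* (syntactic support)."""
    op = expr[0]
    if op == "var":
        return frozenset((expr[1],))
    if op == "const":
        return frozenset()
    out: set[str] = set()
    for sub in expr[1:]:
        out |= support(sub)
    return frozenset(out)


def evaluate(expr: Expr, env: Mapping[str, int]) -> int:
    op = expr[0]
    if op == "const":
        return expr[1]
    if op == "var":
        return env[expr[1]]
    if op == "not":
        return 1 - evaluate(expr[1], env)
    if op == "and":
        for sub in expr[1:]:
            if not evaluate(sub, env):
                return 0
        return 1
    # or
    for sub in expr[1:]:
        if evaluate(sub, env):
            return 1
    return 0


def substitute(expr: Expr, env: Mapping[str, int]) -> Expr:
    """Bind variables in *env* to constants and simplify short circuits."""
    op = expr[0]
    if op == "const":
        return expr
    if op == "var":
        v = env.get(expr[1])
        return expr if v is None else ("const", int(v))
    if op == "not":
        inner = substitute(expr[1], env)
        if inner[0] == "const":
            return ("const", 1 - inner[1])
        return ("not", inner)
    subs = [substitute(sub, env) for sub in expr[1:]]
    zero, one = (0, 1) if op == "and" else (1, 0)
    kept = []
    for sub in subs:
        if sub[0] == "const":
            if sub[1] == zero:
                return ("const", zero)
            continue  # identity element
        kept.append(sub)
    if not kept:
        return ("const", one)
    if len(kept) == 1:
        return kept[0]
    return (op, *kept)


def constant_value(expr: Expr, env: Mapping[str, int] | None = None) -> int | None:
    """Return 0/1 if *expr* is constant over every assignment of the variables
    not bound by *env*, else ``None``.

    Constancy is decided by exhaustive enumeration of the unbound support, so
    vacuous dependence (``x | !x``) is detected.  Cost is ``2**l`` for ``l``
    unbound arguments.
    """
    env = env or {}
    reduced = substitute(expr, env)
    if reduced[0] == "const":
        return reduced[1]
    free = sorted(support(reduced))
    first = None
    for bits in product((0, 1), repeat=len(free)):
        val = evaluate(reduced, dict(zip(free, bits)))
        if first is None:
            first = val
        elif val != first:
            return None
    return first


def depends_on(expr: Expr, var: str) -> bool:
    """Functional (not merely syntactic) dependence of *expr* on *var*.

    True iff flipping *var* changes the value for at least one assignment of
    the other arguments; enumeration over ``2**(l-1)`` assignments.
    """
    if var not in support(expr):
        return False
    others = sorted(support(expr) - {var})
    for bits in product((0, 1), repeat=len(others)):
        env = dict(zip(others, bits))
        env[var] = 0
        v0 = evaluate(expr, env)
        env[var] = 1
        if evaluate(expr, env) != v0:
            return True
    return False


# ---------------------------------------------------------------------------
# rendering

def to_text(expr: Expr, _parent: str = "or") -> str:
    """Serialize to the rule dialect (re-parses to an equivalent tree)."""
    op = expr[0]
    if op == "const":
        return str(expr[1])
    if op == "var":
        return expr[1]
    if op == "not":
        inner = expr[1]
        body = to_text(inner, "not")
        if inner[0] in ("and", "or"):
            body = f"({body})"
        return f"!{body}"
    sep = " & " if op == "and" else " | "
    body = sep.join(to_text(sub, op) for sub in expr[1:])
    if (op == "or" and _parent in ("and", "not")) or (op == "and" and _parent == "not"):
        return f"({body})"
    return body


def to_python_bits(expr: Expr, index: Mapping[str, int], state: str = "x") -> str:
    """Render as a Python int expression over the bits of integer *state*.

    Used to compile fast synchronous steppers; all subterms evaluate to 0/1 so
    ``&``/``|`` coincide with logical connectives.
    """
    op = expr[0]
    if op == "const":
        return str(expr[1])
    if op == "var":
        return f"(({state}>>{index[expr[1]]})&1)"
    if op == "not":
        return f"(1-{to_python_bits(expr[1], index, state)})"
    sep = "&" if op == "and" else "|"
    return "(" + sep.join(to_python_bits(sub, index, state) for sub in expr[1:]) + ")"
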