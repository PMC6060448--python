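"""Synchronous Boolean networks: parsing, evaluation, modification.

A network is a list of named nodes in declaration order, each with a Boolean
transition expression; the state evolves synchronously, ``x := F(x)``.
External-input nodes are self-identity nodes whose values are supplied as
fixings before any analysis; output (marker) nodes stay dynamic but are never
control candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from . import expr as ex
from .expr import Expr, ExprSyntaxError

State = tuple  # tuple of 0/1, one bit per node in declaration order


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class FixedAssignment:
    """A node pinned to a constant, with provenance for reporting."""

    node: str
    value: int
    provenance: str = "control"  # control | mutation | external-input | canalized

    def __post_init__(self):
        if self.value not in (0, 1):
            raise NetworkError(f"fixed value for {self.node!r} must be 0 or 1")


def fixings_to_env(fixings: Iterable[FixedAssignment]) -> dict[str, int]:
    """Collapse fixings to a name->bit map, rejecting conflicts."""
    env: dict[str, int] = {}
    for fx in fixings:
        if fx.node in env and env[fx.node] != fx.value:
            raise NetworkError(f"conflicting fixings for node {fx.node!r}")
        env[fx.node] = fx.value
    return env


@dataclass(frozen=True)
class BooleanNetwork:
    names: tuple[str, ...]
    functions: tuple[Expr, ...]
    inputs: frozenset[str] = frozenset()
    outputs: frozenset[str] = frozenset()
    index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "index", {nm: i for i, nm in enumerate(self.names)})
        if len(self.index) != len(self.names):
            raise NetworkError("duplicate node names")
        for role in (self.inputs, self.outputs):
            for nm in role:
                if nm not in self.index:
                    raise NetworkError(f"declared role for unknown node {nm!r}")
        for nm, f in zip(self.names, self.functions):
            for var in ex.support(f):
                if var not in self.index:
                    raise NetworkError(
                        f"rule for {nm!r} references undeclared node {var!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def max_in_degree(self) -> int:
        """``s``: the maximum number of distinct variables in any rule."""
        return max((len(ex.support(f)) for f in self.functions), default=0)

    def function_of(self, node: str) -> Expr:
        return self.functions[self.index[node]]

    def with_roles(self, inputs: Iterable[str] = (), outputs: Iterable[str] = ()) -> "BooleanNetwork":
        return BooleanNetwork(self.names, self.functions,
                              frozenset(inputs), frozenset(outputs))

    # -- state helpers ------------------------------------------------------

    def state_from_int(self, code: int) -> State:
        return tuple((code >> i) & 1 for i in range(self.n))

    def state_to_int(self, x: Sequence[int]) -> int:
        return sum(b << i for i, b in enumerate(x))

    def state_from_bits(self, bits: str) -> State:
        """Parse the comma-free bit-string form, e.g. ``\"11001010\"``."""
        if len(bits) != self.n or set(bits) - {"0", "1"}:
            raise NetworkError(f"state string must be {self.n} bits of 0/1")
        return tuple(int(b) for b in bits)

    def state_env(self, x: Sequence[int]) -> dict[str, int]:
        return dict(zip(self.names, x))

    # -- dynamics -----------------------------------------------------------

    def compile_step(self, fixings: Iterable[FixedAssignment] = ()) -> "callable":
        """Compile the synchronous update into an int->int function."""
        env = fixings_to_env(fixings)
        parts = []
        for i, (nm, f) in enumerate(zip(self.names, self.functions)):
            if nm in env:
                bit = str(env[nm])
            else:
                bit = ex.to_python_bits(f, self.index)
            parts.append(f"(({bit})<<{i})" if i else f"({bit})")
        src = "lambda x: " + "|".join(parts)
        return eval(src, {"__builtins__": {}})  # noqa: S307 - generated from ASTs


def step(net: BooleanNetwork, x: Sequence[int],
         fixings: Iterable[FixedAssignment] = ()) -> State:
    """One synchronous update; fixed nodes keep their pinned value."""
    env_fix = fixings_to_env(fixings)
    if len(x) != net.n:
        raise NetworkError(f"state has length {len(x)}, expected {net.n}")
    for nm, v in env_fix.items():
        if x[net.index[nm]] != v:
            raise NetworkError(f"state disagrees with fixing {nm}={v}")
    env = net.state_env(x)
    return tuple(
        env_fix[nm] if nm in env_fix else ex.evaluate(f, env)
        for nm, f in zip(net.names, net.functions)
    )


def apply_fixings(net: BooleanNetwork, fixings: Iterable[FixedAssignment],
                  bind: bool = False) -> BooleanNetwork:
    """Return a network in which each fixed node's rule is the constant.

    With ``bind=True`` the fixed values are additionally substituted into all
    other rules, so any dependence on a fixed node disappears from the
    expressions themselves (used when refining the adjacency matrix for
    external inputs and mutations).
    """
    env = fixings_to_env(fixings)
    for nm in env:
        if nm not in net.index:
            raise NetworkError(f"fixing targets unknown node {nm!r}")
    functions = []
    for nm, f in zip(net.names, net.functions):
        if nm in env:
            functions.append(("const", env[nm]))
        elif bind:
            functions.append(ex.substitute(f, env))
        else:
            functions.append(f)
    return replace(net, functions=tuple(functions))


# ---------------------------------------------------------------------------
# rule-file dialect ("targets, factors")

def parse_network(text: str) -> BooleanNetwork:
    """Parse BoolNet-style rule text.

    Header line ``targets, factors`` is optional; comment lines start with
    ``#``; each rule line is ``Name, <expression>``.
    """
    names: list[str] = []
    functions: list[Expr] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise NetworkError(f"line {lineno}: expected 'Name, expression'")
        name, rule = line.split(",", 1)
        name = name.strip()
        if not name or set(name) - ex._NAME_CHARS or name[0].isdigit():
            raise NetworkError(f"line {lineno}: invalid node name {name!r}")
        if name in seen:
            raise NetworkError(f"line {lineno}: duplicate target {name!r}")
        seen.add(name)
        try:
            tree = ex.parse_expression(rule)
        except ExprSyntaxError as err:
            raise NetworkError(f"line {lineno} ({name}): {err}") from err
        names.append(name)
        functions.append(tree)
    if not names:
        raise NetworkError("no rules found")
    return BooleanNetwork(tuple(names), tuple(functions))


def serialize_network(net: BooleanNetwork) -> str:
    lines = ["targets, factors"]
    for nm, f in zip(net.names, net.functions):
        lines.append(f"{nm}, {ex.to_text(f)}")
    return "\n".join(lines) + "\n"


def load_side_config(text: str) -> dict:
    """Side config JSON: inputs/outputs/mutations/uncontrollable declarations."""
    cfg = json.loads(text)
    out = {
        "inputs": list(cfg.get("inputs", [])),
        "outputs": list(cfg.get("outputs", [])),
        "mutations": {k: int(v) for k, v in cfg.get("mutations", {}).items()},
        "uncontrollable": list(cfg.get("uncontrollable", [])),
    }
    return out
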