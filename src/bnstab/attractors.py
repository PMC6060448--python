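"""Attractor analysis of synchronous Boolean networks.

Attractors (fixed points and cycles) are the model's phenotypes.  Exhaustive
enumeration walks the full 2**n state-transition graph; fixed points can also
be found without enumeration by backtracking with constraint propagation, and
large networks can be probed by seeded random sampling of initial states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import expr as ex
from .network import BooleanNetwork, FixedAssignment, fixings_to_env

EXHAUSTIVE_CAP = 22  # 2**22 states ~ 4M, desk-scale


@dataclass(frozen=True)
class Attractor:
    """A synchronous attractor in canonical form.

    ``states`` is the cycle rotated to start at the minimal integer-encoded
    state (length 1 = fixed point); ``basin`` counts states converging to it
    when known.
    """

    states: tuple[tuple, ...]
    basin: int | None = None

    def __eq__(self, other):
        return isinstance(other, Attractor) and self.states == other.states

    def __hash__(self):
        return hash(self.states)

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1


def _canonical(cycle: list[int], net: BooleanNetwork) -> tuple[tuple, ...]:
    k = cycle.index(min(cycle))
    rotated = cycle[k:] + cycle[:k]
    return tuple(net.state_from_int(c) for c in rotated)


def enumerate_attractors(net: BooleanNetwork,
                         fixings: Iterable[FixedAssignment] = (),
                         cap: int = EXHAUSTIVE_CAP,
                         with_basins: bool = True) -> set[Attractor]:
    """Exact attractor set by full transition-graph traversal.

    Basin sizes partition the 2**n states.  Raises if n exceeds ``cap``;
    use :func:`sample_attractors` or :func:`find_fixed_points` beyond it.
    """
    if net.n > cap:
        raise ValueError(
            f"n={net.n} exceeds the exhaustive cap ({cap}); "
            "use sample_attractors or find_fixed_points instead"
        )
    stepf = net.compile_step(fixings)
    size = 1 << net.n
    # attractor id per state; -1 unknown, -2 on current path
    aid = np.full(size, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for start in range(size):
        if aid[start] != -1:
            continue
        path = []
        x = start
        while aid[x] == -1:
            aid[x] = -2
            path.append(x)
            x = stepf(x)
        if aid[x] == -2:  # new cycle discovered on this path
            cyc = path[path.index(x):]
            cid = len(cycles)
            cycles.append(cyc)
        else:
            cid = aid[x]
        for y in path:
            aid[y] = cid
    out = set()
    for cid, cyc in enumerate(cycles):
        basin = int((aid == cid).sum()) if with_basins else None
        out.add(Attractor(_canonical(cyc, net), basin))
    return out


def simulate_to_attractor(net: BooleanNetwork,
                          fixings: Iterable[FixedAssignment] = (),
                          x0=None) -> tuple[Attractor, int]:
    """Iterate from ``x0`` until a state repeats; return (attractor, transient)."""
    stepf = net.compile_step(fixings)
    x = net.state_to_int(x0)
    seen: dict[int, int] = {}
    path: list[int] = []
    while x not in seen:
        seen[x] = len(path)
        path.append(x)
        x = stepf(x)
    start = seen[x]
    return Attractor(_canonical(path[start:], net)), start


def find_fixed_points(net: BooleanNetwork,
                      fixings: Iterable[FixedAssignment] = ()) -> set[tuple]:
    """All states with F(x) = x, by backtracking with constraint propagation.

    Nodes are assigned in declaration order; after each assignment, any rule
    that has become constant forces its target's value, recursively.  Works
    far beyond the exhaustive enumeration cap on sparse networks.
    """
    base = fixings_to_env(fixings)

    supports = [ex.support(f) for f in net.functions]
    dependants: dict[str, list[int]] = {nm: [] for nm in net.names}
    for i, sup in enumerate(supports):
        for v in sup:
            dependants[v].append(i)

    def propagate(env: dict[str, int], queue: list[int]) -> bool:
        """Force consequences of newly decided nodes; False on contradiction."""
        while queue:
            i = queue.pop()
            nm = net.names[i]
            f = net.functions[i] if nm not in base else ("const", base[nm])
            val = ex.constant_value(f, env)
            if val is None:
                continue
            if nm in env:
                if env[nm] != val:
                    return False
            else:
                env[nm] = val
                queue.extend(dependants[nm])
                queue.append(i)
        return True

    results: set[tuple] = set()

    def backtrack(env: dict[str, int]) -> None:
        nxt = next((nm for nm in net.names if nm not in env), None)
        if nxt is None:
            results.add(tuple(env[nm] for nm in net.names))
            return
        for v in (0, 1):
            trial = dict(env)
            trial[nxt] = v
            queue = [net.index[nxt]] + list(dependants[nxt])
            if propagate(trial, queue):
                backtrack(trial)

    env0 = dict(base)
    if propagate(env0, list(range(net.n))):
        backtrack(env0)
    return results


def sample_attractors(net: BooleanNetwork,
                      fixings: Iterable[FixedAssignment] = (),
                      n_samples: int = 1000, seed: int = 0) -> set[Attractor]:
    """Attractors reached from seeded random initial states (a subset of the
    exact attractor set; reproducible given the seed)."""
    rng = np.random.default_rng(seed)
    env = fixings_to_env(fixings)
    stepf = net.compile_step(fixings)
    out: set[Attractor] = set()
    fixed_mask = 0
    fixed_bits = 0
    for nm, v in env.items():
        fixed_mask |= 1 << net.index[nm]
        fixed_bits |= v << net.index[nm]
    for _ in range(n_samples):
        x = int(rng.integers(0, 1 << net.n))
        x = (x & ~fixed_mask) | fixed_bits
        seen: dict[int, int] = {}
        path: list[int] = []
        while x not in seen:
            seen[x] = len(path)
            path.append(x)
            x = stepf(x)
        out.add(Attractor(_canonical(path[seen[x]:], net)))
    return out
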