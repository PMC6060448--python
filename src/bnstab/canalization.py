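"""Cascading canalization: C_j(P;u) sets and canalization numbers T_j.

Fixing one variable can force a transition function to a constant; that
constant can in turn force further functions, and so on.  The cascade closure
is the fixpoint of this propagation.  ``C_j(P;u)`` is the index set of all
transition functions forced constant by setting ``x_j = u`` on top of the
fixed context ``P`` (excluding ``j`` itself); the canalization number
``T_j(P,Q) = max(|C_j(P;0) ∩ Q|, |C_j(P;1) ∩ Q|)`` scores how strongly a
candidate control input collapses the rest of the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

from . import expr as ex
from .network import BooleanNetwork, FixedAssignment, fixings_to_env


@dataclass(frozen=True)
class CanalizationResult:
    node: str
    value: int
    closure: Mapping[str, int]       # node -> forced bit, j excluded
    canalized: frozenset[str]        # C_j(P;u), names

    @property
    def size(self) -> int:
        return len(self.canalized)

    def restricted(self, Q: Iterable[str]) -> frozenset[str]:
        return self.canalized & frozenset(Q)


@dataclass(frozen=True)
class CanalizationNumber:
    node: str
    T: int
    u_star: int
    sizes: tuple[int, int]           # (|C∩Q| for u=0, for u=1)
    results: tuple[CanalizationResult, CanalizationResult]


def cascade_closure(net: BooleanNetwork,
                    fixed: Iterable[FixedAssignment] | Mapping[str, int]) -> dict[str, int]:
    """Fixpoint of constant propagation; independent of scan order.

    A non-fixed node ``h`` joins the closure with value ``v`` when ``f_h``
    evaluates to ``v`` for every assignment of its not-yet-forced arguments.
    Constancy is checked by enumeration (cost <= 2**s per node), so vacuous
    dependence is handled.  Returns only the newly forced nodes.
    """
    forced = dict(fixed) if isinstance(fixed, Mapping) else fixings_to_env(fixed)
    given = set(forced)
    changed = True
    while changed:
        changed = False
        for nm, f in zip(net.names, net.functions):
            if nm in forced:
                continue
            val = ex.constant_value(f, forced)
            if val is not None:
                forced[nm] = val
                changed = True
    return {nm: v for nm, v in forced.items() if nm not in given}


def canalized_set(net: BooleanNetwork, P: Iterable[FixedAssignment],
                  j: str, u: int) -> CanalizationResult:
    """C_j(P;u): the cascade closure of P plus {x_j := u}, minus j itself."""
    env = fixings_to_env(P)
    if j in env:
        raise ValueError(f"candidate {j!r} is already fixed in P")
    env[j] = u
    closure = cascade_closure(net, env)
    closure.pop(j, None)
    return CanalizationResult(j, u, closure, frozenset(closure))


def canalization_number(net: BooleanNetwork, P: Iterable[FixedAssignment],
                        Q: Iterable[str], j: str,
                        u_tie: int = 1) -> CanalizationNumber:
    """T_j(P,Q) with the maximizing value u*; ties resolved to ``u_tie``."""
    Qs = frozenset(Q)
    r0 = canalized_set(net, P, j, 0)
    r1 = canalized_set(net, P, j, 1)
    s0, s1 = len(r0.restricted(Qs)), len(r1.restricted(Qs))
    if s0 == s1:
        u_star = u_tie
    else:
        u_star = 0 if s0 > s1 else 1
    return CanalizationNumber(j, max(s0, s1), u_star, (s0, s1), (r0, r1))


def closure_to_json(net: BooleanNetwork, fixed: Mapping[str, int],
                    result: CanalizationNumber) -> str:
    best = result.results[result.u_star]
    payload = {
        "fixed": dict(fixed),
        "closure": dict(best.closure),
        "C": sorted(best.canalized),
        "T": result.T,
        "u_star": result.u_star,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
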