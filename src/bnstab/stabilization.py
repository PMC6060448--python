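"""Greedy selection of constant control inputs that globally stabilize a
synchronous Boolean network.

The strategy: reorder nodes so the adjacency matrix is as close as possible
to strictly triangular, then repeatedly pin the candidate variable whose
column (row, in the upper-triangular variant) carries the most offending
entries, breaking ties by canalization number.  Pinned and canalized nodes
have their rows and columns zeroed; once the working matrix is strictly
triangular the influence graph of the controlled network is acyclic, its
Boolean adjacency is nilpotent, and the network converges to a unique fixed
point from every initial state.

External inputs and mutations are bound into the rules beforehand (their
rows/columns vanish and anything their cascade forces is zeroed a priori);
declared outputs and uncontrollable nodes are never candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .adjacency import (AdjacencyMatrix, compute_adjacency, is_strictly_triangular,
                        nilpotency_index, permute_by_col_norm, permute_by_row_norm)
from .attractors import enumerate_attractors, simulate_to_attractor
from .canalization import canalization_number, cascade_closure
from .network import (BooleanNetwork, FixedAssignment, NetworkError,
                      apply_fixings, fixings_to_env)


class StabilizationError(RuntimeError):
    pass


@dataclass
class IterationRecord:
    K: tuple[str, ...]
    j_star: str
    u_star: int
    T: int
    canalized: tuple[str, ...]
    matrix: AdjacencyMatrix


@dataclass
class ControlContext:
    """Evolving algorithm state (one instance per run, mutated in place)."""

    P: list[tuple[str, int]] = field(default_factory=list)
    Q: set[str] = field(default_factory=set)
    Q_f: frozenset[str] = frozenset()
    ledger: dict[str, int] = field(default_factory=dict)   # canalized values
    trace: list[IterationRecord] = field(default_factory=list)


@dataclass(frozen=True)
class StabilizationResult:
    controls: tuple[tuple[str, int], ...]
    mode: str
    matrix: AdjacencyMatrix            # final permuted working matrix
    permutation: tuple[str, ...]
    fixed_point: tuple | None
    trace: tuple[IterationRecord, ...]
    steps: int | None                  # convergence horizon observed

    @property
    def control_fixings(self) -> tuple[FixedAssignment, ...]:
        return tuple(FixedAssignment(nm, u, "control") for nm, u in self.controls)


def _resolve_options(net: BooleanNetwork,
                     input_values: Mapping[str, int] | None,
                     mutations: Mapping[str, int] | None,
                     uncontrollable: Iterable[str] | None):
    input_values = dict(input_values or {})
    for nm in net.inputs:
        input_values.setdefault(nm, 0)
    for nm in input_values:
        if nm not in net.index:
            raise NetworkError(f"unknown input node {nm!r}")
    mutations = {nm: int(v) for nm, v in (mutations or {}).items()}
    overlap = set(input_values) & set(mutations)
    for nm in overlap:
        if input_values[nm] != mutations[nm]:
            raise NetworkError(f"inconsistent input/mutation fixing for {nm!r}")
    q_f = frozenset(uncontrollable or ())
    return input_values, mutations, q_f


def _context_fixings(input_values, mutations, ledger, controls):
    out = [FixedAssignment(nm, v, "external-input") for nm, v in input_values.items()]
    out += [FixedAssignment(nm, v, "mutation") for nm, v in mutations.items()]
    out += [FixedAssignment(nm, v, "canalized") for nm, v in ledger.items()]
    out += [FixedAssignment(nm, u, "control") for nm, u in controls]
    return out


def _run(net: BooleanNetwork, mode: str,
         input_values: Mapping[str, int] | None = None,
         mutations: Mapping[str, int] | None = None,
         uncontrollable: Iterable[str] | None = None,
         u_tie_rule: int = 1,
         repermute: bool = False,
         compute_fixed_point: bool = True) -> StabilizationResult:
    input_values, mutations, q_f = _resolve_options(
        net, input_values, mutations, uncontrollable)

    # Step 0: bind input values and mutations into the rules.  Mutations are
    # additionally refined a priori: everything their cascade forces is bound
    # and excluded from candidacy.  Input-canalized nodes keep their columns
    # and stay eligible (their rows vanish naturally as constants).
    pre_env = dict(input_values)
    pre_env.update(mutations)
    mut_closure = cascade_closure(net, mutations) if mutations else {}
    bound = apply_fixings(
        net,
        [FixedAssignment(nm, v) for nm, v in {**pre_env, **mut_closure}.items()],
        bind=True,
    )

    ctx = ControlContext(Q_f=q_f)
    ctx.ledger.update(mut_closure)
    removed = set(pre_env) | set(mut_closure) | set(net.inputs) | set(net.outputs)
    ctx.Q = set(net.names) - removed - set(q_f)

    A = compute_adjacency(bound)
    # input and output variables are removed from the matrix entries
    for nm in set(net.inputs) | set(net.outputs):
        k = A.labels.index(nm)
        A.matrix[k, :] = False
        A.matrix[:, k] = False

    def permuted(mat: AdjacencyMatrix) -> AdjacencyMatrix:
        return permute_by_row_norm(mat) if mode == "lower" else permute_by_col_norm(mat)

    def d_score(mat: AdjacencyMatrix, name: str) -> int:
        k = mat.labels.index(name)
        if mode == "lower":   # partial column sum d(a_j^c)
            return int(mat.matrix[: k + 1, k].sum())
        return int(mat.matrix[k, : k + 1].sum())   # partial row sum d(a_i^r)

    # Step 1: permute and prune candidates whose partial sum is already zero.
    A = permuted(A)
    ctx.Q -= {nm for nm in set(ctx.Q) if d_score(A, nm) == 0}

    def triangular(mat):
        return is_strictly_triangular(mat, mode)

    iterations = 0
    while not triangular(A):
        iterations += 1
        if iterations > net.n:
            raise StabilizationError("iteration count exceeded n")  # pragma: no cover
        if repermute and iterations > 1:
            A = permuted(A)
        if not ctx.Q:
            raise StabilizationError(
                "candidate set exhausted before the matrix became triangular")
        # Step 2: best partial sum, then best canalization number.
        scores = {nm: d_score(A, nm) for nm in ctx.Q}
        best = max(scores.values())
        K = sorted((nm for nm, s in scores.items() if s == best),
                   key=lambda nm: A.labels.index(nm))
        context = _context_fixings(input_values, mutations, ctx.ledger, ctx.P)
        numbers = {nm: canalization_number(net, context, ctx.Q, nm, u_tie_rule)
                   for nm in K}
        j_star = max(K, key=lambda nm: (numbers[nm].T, -A.labels.index(nm)))
        cn = numbers[j_star]
        u_star = cn.u_star
        result = cn.results[u_star]
        canal_in_q = result.restricted(ctx.Q)
        # Step 3: zero rows/columns of j* and of everything its cascade
        # forces (canalized nodes are eventually constant, so their edges
        # are disconnected whether or not they were candidates).
        for nm in {j_star} | set(result.canalized):
            k = A.labels.index(nm)
            A.matrix[k, :] = False
            A.matrix[:, k] = False
        ctx.P.append((j_star, u_star))
        ctx.Q -= {j_star} | set(result.canalized)
        ctx.ledger.update(result.closure)
        ctx.trace.append(IterationRecord(
            tuple(K), j_star, u_star, cn.T, tuple(sorted(canal_in_q)),
            AdjacencyMatrix(A.matrix.copy(), A.labels, A.perm)))

    fixed_point = None
    steps = None
    if compute_fixed_point:
        fixed_point, steps = _settle(net, input_values, mutations, ctx.P)

    return StabilizationResult(
        controls=tuple(ctx.P), mode=mode, matrix=A, permutation=A.labels,
        fixed_point=fixed_point, trace=tuple(ctx.trace), steps=steps)


def _settle(net, input_values, mutations, controls):
    """Simulate the controlled network from the all-zero state to its unique
    fixed point (guaranteed by triangularity of the working matrix)."""
    fixings = [FixedAssignment(nm, v, "external-input") for nm, v in input_values.items()]
    fixings += [FixedAssignment(nm, v, "mutation") for nm, v in mutations.items()]
    fixings += [FixedAssignment(nm, u, "control") for nm, u in controls]
    env = fixings_to_env(fixings)
    x0 = tuple(env.get(nm, 0) for nm in net.names)
    attr, transient = simulate_to_attractor(net, fixings, x0)
    if not attr.is_fixed_point:  # pragma: no cover - excluded by triangularity
        raise StabilizationError("controlled network did not reach a fixed point")
    return attr.states[0], transient


def algorithm1(net: BooleanNetwork, **options) -> StabilizationResult:
    """Controls that make the permuted adjacency strictly lower triangular."""
    return _run(net, "lower", **options)


def algorithm2(net: BooleanNetwork, **options) -> StabilizationResult:
    """Controls that make the permuted adjacency strictly upper triangular."""
    return _run(net, "upper", **options)


def _convergence_horizon(net, fixings, target: int) -> int:
    """Largest number of steps any initial state needs to hit ``target``.

    All 2**n initial states are considered: a controlled node's rule is the
    constant, but its initial value is free and snaps to the control after
    one update.
    """
    stepf = net.compile_step(fixings)
    depth: dict[int, int] = {target: 0}
    worst = 0
    for x in range(1 << net.n):
        path = []
        y = x
        while y not in depth:
            path.append(y)
            y = stepf(y)
        base = depth[y]
        for k, st in enumerate(reversed(path), start=1):
            depth[st] = base + k
        if path:
            worst = max(worst, depth[x])
    return worst


@dataclass(frozen=True)
class StabilityReport:
    is_stable: bool
    fixed_point: tuple | None
    steps: int | None
    n_attractors: int | None
    certificate: str  # "exhaustive" | "nilpotent"


def verify_global_stability(net: BooleanNetwork,
                            P: Sequence[tuple[str, int]] | Iterable[FixedAssignment],
                            fixings: Iterable[FixedAssignment] = (),
                            exhaustive_cap: int = 16) -> StabilityReport:
    """Check that the controls P globally stabilize the network.

    For small n every state is enumerated and a single length-1 attractor is
    required; beyond the cap, nilpotency of the controlled adjacency (a
    sufficient condition) is checked and the fixed point is found by
    simulation.
    """
    ctrl = [p if isinstance(p, FixedAssignment) else FixedAssignment(p[0], p[1])
            for p in P]
    all_fix = list(fixings) + ctrl
    if net.n <= exhaustive_cap:
        attrs = enumerate_attractors(net, all_fix)
        stable = len(attrs) == 1 and next(iter(attrs)).is_fixed_point
        fp = None
        steps = None
        if stable:
            attr = next(iter(attrs))
            fp = attr.states[0]
            steps = _convergence_horizon(net, all_fix, net.state_to_int(fp))
        return StabilityReport(stable, fp, steps, len(attrs), "exhaustive")
    closure = cascade_closure(net, all_fix)
    closed = all_fix + [FixedAssignment(nm, v, "canalized")
                        for nm, v in closure.items()]
    bound = apply_fixings(net, closed, bind=True)
    A = compute_adjacency(bound)
    env = fixings_to_env(all_fix)
    x0 = tuple(env.get(nm, 0) for nm in net.names)
    attr, steps = simulate_to_attractor(net, all_fix, x0)
    fp = attr.states[0] if attr.is_fixed_point else None
    if nilpotency_index(A) is not None:
        return StabilityReport(attr.is_fixed_point, fp, steps, None, "nilpotent")
    # cascade leaves a small self-contained subsystem: enumerate it exactly
    residual = [nm for nm in net.names if nm not in fixings_to_env(closed)]
    if len(residual) <= exhaustive_cap:
        sub = BooleanNetwork(tuple(residual),
                             tuple(bound.function_of(nm) for nm in residual))
        sub_attrs = enumerate_attractors(sub)
        stable = (len(sub_attrs) == 1
                  and next(iter(sub_attrs)).is_fixed_point
                  and attr.is_fixed_point)
        return StabilityReport(stable, fp, steps, len(sub_attrs),
                               "reduced-exhaustive")
    return StabilityReport(False, fp, steps, None, "inconclusive")
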