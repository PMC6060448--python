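"""Two-stage sequential control: stabilize globally, then steer by inputs.

Stage 1 pins the constant controls returned by the triangularization
algorithm, collapsing the attractor landscape to one fixed point ``x*``.
Stage 2 releases those controls, allocates ``x*`` as the initial state, and
applies each of the ``2**m`` external-input combinations in turn; an outcome
is acceptable when it is a fixed point whose marker nodes match the desired
phenotype.  Among acceptable combinations the one activating the fewest
inputs is selected.  Mutations stay fixed throughout both stages.

Several mutation profiles may be given; the selected combination must then
be acceptable under every profile (the joint minimal perturbation).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

from .attractors import Attractor, simulate_to_attractor
from .network import BooleanNetwork, FixedAssignment, NetworkError
from .stabilization import StabilizationResult, algorithm1, algorithm2


@dataclass(frozen=True)
class PhenotypeSpec:
    """Marker constraints as (output-node name, required bit) pairs."""

    markers: tuple[tuple[str, int], ...]

    @classmethod
    def from_mapping(cls, m: Mapping[str, int]) -> "PhenotypeSpec":
        return cls(tuple((k, int(v)) for k, v in m.items()))

    def validate(self, net: BooleanNetwork) -> None:
        for nm, _ in self.markers:
            if nm not in net.index:
                raise NetworkError(f"marker node {nm!r} not in network")


@dataclass(frozen=True)
class OutcomeVerdict:
    satisfied: bool
    marker_values: Mapping[str, int] | None   # None for cyclic outcomes
    is_cycle: bool


@dataclass(frozen=True)
class OutcomeRow:
    inputs: tuple[tuple[str, int], ...]
    attractor: Attractor
    verdict: OutcomeVerdict


@dataclass(frozen=True)
class SequentialControlResult:
    stage1: tuple[StabilizationResult, ...]      # one per mutation profile
    tables: tuple[tuple[OutcomeRow, ...], ...]   # one 2**m table per profile
    selected: tuple[tuple[str, int], ...] | None
    n_activated: int | None
    input_names: tuple[str, ...]


def evaluate_outcome(attractor: Attractor, phenotype: PhenotypeSpec,
                     net: BooleanNetwork,
                     allow_constant_cycles: bool = False) -> OutcomeVerdict:
    """Fixed point: compare marker bits.  Cycle: unsatisfied (unless the
    permissive flag is set and every marker is constant along the cycle)."""
    if not attractor.is_fixed_point:
        if allow_constant_cycles:
            vals = {}
            ok = True
            for nm, want in phenotype.markers:
                idx = net.index[nm]
                bits = {st[idx] for st in attractor.states}
                if len(bits) != 1:
                    ok = False
                    break
                vals[nm] = bits.pop()
                ok = ok and vals[nm] == want
            if ok:
                return OutcomeVerdict(True, vals, True)
        return OutcomeVerdict(False, None, True)
    state = attractor.states[0]
    vals = {nm: state[net.index[nm]] for nm, _ in phenotype.markers}
    satisfied = all(vals[nm] == want for nm, want in phenotype.markers)
    return OutcomeVerdict(satisfied, vals, False)


def run_sequential(net: BooleanNetwork, phenotype: PhenotypeSpec,
                   mutations: Mapping[str, int] | Sequence[Mapping[str, int]] | None = None,
                   mode: str = "lower",
                   stage1_inputs: Mapping[str, int] | None = None,
                   uncontrollable: Iterable[str] | None = None,
                   allow_constant_cycles: bool = False) -> SequentialControlResult:
    """Full sequential-control scheme over all 2**m input combinations."""
    phenotype.validate(net)
    input_names = tuple(nm for nm in net.names if nm in net.inputs)
    if not input_names:
        raise NetworkError("network declares no external inputs")
    if mutations is None:
        profiles: list[dict[str, int]] = [{}]
    elif isinstance(mutations, Mapping):
        profiles = [dict(mutations)]
    else:
        profiles = [dict(p) for p in mutations]

    algo = algorithm1 if mode == "lower" else algorithm2
    stage1 = []
    tables = []
    satisfied_sets: list[set[tuple[int, ...]]] = []
    for prof in profiles:
        res = algo(net, input_values=stage1_inputs, mutations=prof,
                   uncontrollable=uncontrollable)
        stage1.append(res)
        x_star = res.fixed_point
        rows = []
        good: set[tuple[int, ...]] = set()
        for combo in product((0, 1), repeat=len(input_names)):
            fixings = [FixedAssignment(nm, v, "external-input")
                       for nm, v in zip(input_names, combo)]
            fixings += [FixedAssignment(nm, v, "mutation") for nm, v in prof.items()]
            env = {nm: v for nm, v in zip(input_names, combo)}
            env.update(prof)
            x0 = tuple(env.get(nm, b) for nm, b in zip(net.names, x_star))
            attr, _ = simulate_to_attractor(net, fixings, x0)
            verdict = evaluate_outcome(attr, phenotype, net, allow_constant_cycles)
            rows.append(OutcomeRow(tuple(zip(input_names, combo)), attr, verdict))
            if verdict.satisfied:
                good.add(combo)
        tables.append(tuple(rows))
        satisfied_sets.append(good)

    joint = set.intersection(*satisfied_sets) if satisfied_sets else set()
    selected = None
    n_act = None
    if joint:
        best = min(joint, key=lambda c: (sum(c), c))
        selected = tuple(zip(input_names, best))
        n_act = sum(best)
    return SequentialControlResult(tuple(stage1), tuple(tables), selected,
                                   n_act, input_names)
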