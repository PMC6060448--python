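# Methods

## Model and update semantics

A network is an ordered list of named binary variables with one transition
expression each; updates are synchronous, `x := F(x)`.  Asynchronous
semantics are out of scope.  Node order is declaration order in the rule
file and fixes every matrix, vector and permutation in the package, so runs
are reproducible byte for byte.

External inputs are self-identity nodes (`u, u`); their values are supplied
as fixings before analysis.  Output (marker) nodes stay dynamic but are
never control candidates.  Mutations are fixings with provenance
`mutation`: knockout pins a node to 0, constitutive activation to 1.  A
*control* replaces the node's rule by a constant; the node's initial state
value remains free and snaps to the control after one update, which is also
the convention used when counting convergence steps.

## Adjacency matrices

`compute_adjacency` implements the functional-dependence test: `a_ij = 1`
iff flipping `x_j` changes `f_i` for some assignment of the other
*syntactic* arguments (2^(l−1) evaluations for in-degree l, never 2^(n−1);
vacuous dependence such as `x | !x` is correctly reported as 0).  A fixed
node's row is zero because its rule is a constant, but its **column is
kept**: other rules still read the variable over the full state space.
This matches the controlled 4-node example, whose printed matrix retains
the fixed node's column and has Boolean nilpotency index 4.  Value
*binding* (`bind=True` / `apply_fixings(..., bind=True)`) is the separate
operation that substitutes fixed values into every rule; it zeroes the
fixed columns and prunes edges that a propagated constant makes vacuous,
and is what the stabilization algorithms apply to external inputs and
mutations before deriving their working matrix.

Nilpotency is decided by Boolean powers up to `k = n` (a nilpotent Boolean
matrix of size n vanishes by power n, so the search is exact).  Acyclicity
of the influence graph (edge `j -> i` when `a_ij = 1`) is delegated to
networkx and must — and, property-tested, does — agree with nilpotency and
with brute-force permutability to strict triangular form.

## Cascading canalization

The closure is the fixpoint of constant propagation: a node joins with
value `v` when its rule evaluates to `v` for *every* assignment of its
not-yet-forced arguments (enumeration over the unforced support, ≤ 2^s per
node).  The result is order-independent and is computed identically no
matter which module asks for it.  `C_j(P;u)` excludes `j` itself: the
candidate's own rule is overridden by the pin anyway, and counting it would
shift every candidate equally.  When both values canalize equally,
`u* = 1` is chosen (configurable); the choice is arbitrary in the theory
and fixed here for determinism.

## The stabilization algorithms

Both variants share one engine.  Step 0 binds input values and mutations
into the rules; mutations are additionally refined a priori — everything
their cascade forces is bound, excluded from candidacy, and entered into
the canalized-value ledger.  Input-canalized nodes keep their columns and
their candidacy: only the mutation cascade is pre-excluded, which is what
lets the candidate set start as "all free variables" on the biological
fixtures.  Rows and columns of declared inputs and outputs are zeroed in
the working matrix (the removal convention); uncontrollable nodes are
dropped from the candidate set but keep their matrix entries, since their
cycles still must be broken through other selections.

Step 1 permutes symmetrically by ascending row norm (lower mode) or column
norm (upper mode) with a *stable* sort — ties keep declaration order — and
prunes candidates whose partial sum `d` is zero.  The loop then selects the
candidate maximizing `d`, breaking ties by canalization number and then by
permuted position; zeroes the rows and columns of the selection and of
*everything its cascade forces* (canalized nodes are eventually constant,
so their edges are disconnected whether or not they were candidates — this
also makes the run robust when an output or uncontrollable node is
canalized); and repeats, by default without re-permuting (`repermute=True`
re-sorts each iteration).  Termination: each iteration strictly shrinks the
candidate set; if it empties before triangularity (possible only with
uncontrollable-node constraints), the failure is raised explicitly rather
than patched over.

The fixed point `x*` is found by simulating the controlled network from
the all-zero state; triangularity guarantees arrival.

### What the greedy selection does *not* guarantee

The returned control set is sufficient, not minimal, and its identity is
sensitive to the stable tie order and to single-edge differences in the
model: near-tied hubs (e.g. CTNNB1 vs p53 in the metastasis model, PI3K vs
GRB2 in the MAPK model) can swap places under a different node ordering.
The package therefore treats *soundness* as the contract — every returned
set is verified to yield a unique fixed point — and exposes
`verify_global_stability` to certify any externally proposed set (the
published single-target solutions p53 = 1 and p38 = 1 & GRB2 = 1 are
certified this way in the test suite).

## Verification

For n ≤ 16 (configurable) verification enumerates all 2^n states and
requires exactly one attractor of length 1; the reported step count is the
worst case over all initial states.  Beyond that cap the certificate is
nilpotency of the adjacency after binding the cascade closure of all
fixings (sound: closure nodes are eventually constant from any initial
state).  When the cascade leaves a small self-contained residual subsystem
whose matrix is not nilpotent — the MAPK p53–MDM2–PTEN–AKT module under
p14-knockout mutations is the motivating case — the residual is enumerated
exhaustively instead; convergence there is dynamical rather than
canalizing, and the certificate is labelled `reduced-exhaustive`.

## Attractor analysis

Exhaustive enumeration compiles the update into an integer-to-integer map
and walks every state with path memoization (default cap n ≤ 22; basin
sizes always partition 2^n).  Fixed points beyond the cap come from
backtracking with constraint propagation: assign variables in declaration
order, force any rule that has become constant, backtrack on contradiction;
self-identity inputs simply branch, so input configurations are explored
jointly — the nine fixed points reported for the metastasis model count all
input combinations, which is how the published analyses count them.  Sampling
uses one seeded `numpy` generator and returns a subset of the exact set;
attractor identity is the minimal rotation of the integer-encoded cycle.

## Sequential control

Stage 2 starts exactly at `x*` with the stage-1 controls released and the
mutation fixings kept (mutations are physical lesions, not therapies).
Cyclic outcomes never satisfy a phenotype by default, matching how the
published case studies tabulate them; `allow_constant_cycles=True` relaxes this for
cycles whose markers are constant.  Minimal perturbation means fewest
inputs set to 1, with lexicographic tie-break in declared input order.
Several mutation profiles may be supplied; the selection must then satisfy
all of them, which reproduces the published joint choice
`DNA_damage = TGFBR_stimulus = 1` for the two p14-knockout MAPK profiles
(either profile alone admits a cheaper solution).

## Packaged models

The two biological rule files are transcriptions of published logical
models — the Cohen et al. 2015 metastasis influence network and the
Grieco et al. 2013 MAPK network — validated against the published tables the
package reproduces: the printed AKT1 rule, the complete per-input
fixed-point tables of both case studies, the eight-function p53
canalization set, the nine-fixed-point count, the five input-tracking
variables, and the full 32-row sequential-control outcome table.  Two MAPK
rules are under-determined by the fixed-point tables alone (the AP1 arm of
the MEK1/2 inhibition and the MDM2 arm of PTEN regulation); they are fixed
to the variants required by the dynamical behaviour of the published
mutant cases.  Operator precedence in transcription follows `!` > `&` >
`|`.

## The random-network generator

`random_network` emulates the sparse regime of biological logical models
(average in-degree around two): each non-input node draws its in-degree
uniformly from 1..s (default s = 2, property suites use s ≤ 3), regulators
uniformly without replacement (self-loops allowed), and a truth table with
output bias p (default 0.5), rendered as a minterm DNF.  Everything derives
from one seed.  What it does not emulate: scale-free degree tails,
enrichment for canalizing rules, or correlated co-regulation found in
curated models — so the soundness sweep demonstrates correctness of the
algorithmic guarantee on generic sparse logic, not performance statistics
on realistic biology; the two transcribed models cover the latter.

## Problem sizes and numerical choices

Test-suite and acceptance runs use the in-study sizes: the 8- and 4-node
benchmark networks exhaustively; the 32-node metastasis model via
constraint-propagation fixed points and closure-certified stability; the
53-node MAPK model via reduced certificates and 16-combination sweeps; 200
seeded random networks (n ≤ 12, s ≤ 3) against the exhaustive oracle; and
brute-force permutation checks at n ≤ 6 (≤ 720 permutations).  There is no
floating-point arithmetic anywhere in the method — all quantities are
integer counts — so no tolerances apply; determinism is exercised by
repeated-run identity tests.
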