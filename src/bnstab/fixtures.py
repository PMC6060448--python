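"""Bundled networks and a seeded random sparse network generator.

Ships two small synthetic benchmark networks used throughout the test suite,
transcriptions of two published signalling models (the Cohen et al. 2015
metastasis influence network and the Grieco et al. 2013 MAPK cancer cell
fate network), and a reproducible generator of random sparse Boolean
networks for property suites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .network import BooleanNetwork, parse_network, load_side_config

_EXAMPLE1 = """
targets, factors
x1, !x3 & x7 & !x8
x2, (x5 | x6) & !x8
x3, x8
x4, x2 & !x7
x5, x2 | x4
x6, x3 & !x8
x7, x2 & !x8
x8, !(x1 | x2) & (x4 | x7)
"""

_EXAMPLE2 = """
targets, factors
x1, x2 | x3
x2, !x4
x3, x2 & x3
x4, !x3
"""


def example1_network() -> BooleanNetwork:
    """The 8-node synthetic benchmark network.

    Uncontrolled it has two fixed points and one 2-cycle; pinning x8 = 1
    globally stabilizes it to (0,0,1,0,0,0,0,1).
    """
    return parse_network(_EXAMPLE1)


def example2_network() -> BooleanNetwork:
    """The 4-node benchmark network; x3 = 1 stabilizes it to (1,1,1,0)."""
    return parse_network(_EXAMPLE2)


def load_model(name: str) -> BooleanNetwork:
    """Load a packaged biological model: ``"metastasis"`` or ``"mapk"``.

    The rule files are transcriptions of the published logical models
    (Cohen et al. 2015; Grieco et al. 2013) with input/output roles attached
    from the side configs.
    """
    if name not in ("metastasis", "mapk"):
        raise ValueError(f"unknown model {name!r}; choose 'metastasis' or 'mapk'")
    pkg = resources.files("bnstab.models")
    rules = (pkg / f"{name}.bnet").read_text()
    cfg = load_side_config((pkg / f"{name}.json").read_text())
    net = parse_network(rules)
    return net.with_roles(cfg["inputs"], cfg["outputs"])


@dataclass(frozen=True)
class GeneratorConfig:
    """Random sparse network parameters.

    ``n`` nodes; each non-input node draws its in-degree uniformly from
    1..``s`` and a random truth table with P(output=1) = ``p``.  Biological
    networks are sparse (average degree around two), so small ``s`` is the
    realistic regime.
    """

    n: int
    s: int = 2
    p: float = 0.5
    seed: int = 0
    input_fraction: float = 0.0

    def __post_init__(self):
        if not (1 <= self.s <= max(1, self.n - 1)):
            raise ValueError("require 1 <= s <= n - 1")
        if not (0.0 < self.p < 1.0):
            raise ValueError("require 0 < p < 1")


def random_network(cfg: GeneratorConfig) -> BooleanNetwork:
    """Generate a reproducible random sparse Boolean network.

    The first ``round(input_fraction * n)`` nodes are self-identity external
    inputs.  Truth tables are rendered as minterm DNF expressions (or a
    constant when the table is degenerate).
    """
    rng = np.random.default_rng(cfg.seed)
    names = tuple(f"v{i+1}" for i in range(cfg.n))
    n_inputs = int(round(cfg.input_fraction * cfg.n))
    lines = ["targets, factors"]
    for i, nm in enumerate(names):
        if i < n_inputs:
            lines.append(f"{nm}, {nm}")
            continue
        k = int(rng.integers(1, cfg.s + 1))
        regs = [names[j] for j in rng.choice(cfg.n, size=k, replace=False)]
        table = rng.random(2 ** k) < cfg.p
        if table.all():
            rule = "1"
        elif not table.any():
            rule = "0"
        else:
            terms = []
            for row, on in enumerate(table):
                if not on:
                    continue
                lits = [
                    reg if (row >> b) & 1 else f"!{reg}"
                    for b, reg in enumerate(regs)
                ]
                terms.append("(" + " & ".join(lits) + ")")
            rule = " | ".join(terms)
        lines.append(f"{nm}, {rule}")
    net = parse_network("\n".join(lines))
    return net.with_roles(inputs=names[:n_inputs])
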