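"""Seeded random Boolean networks for property testing.

Fixtures are small (the brute-force oracle must stay cheap) and
reproducible: the same spec and seed always generate the same network.
Rules are built from random truth tables over randomly chosen regulators,
rendered as disjunctive normal form expressions so they round-trip through
the text format like any hand-written model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .netcore import And, BooleanNetwork, Const, Expr, NetworkError, Not, Or, Var

__all__ = ["RandomNetworkSpec", "generate_random_network"]


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Shape of a random fixture network.

    ``bias`` is the probability of a 1 in each truth-table row; in-degrees
    are drawn uniformly from ``indegree_range`` (clipped to n).
    """

    n: int
    seed: int
    indegree_range: tuple = (1, 4)
    bias: float = 0.5

    def __post_init__(self):
        if self.n < 1 or self.n > 20:
            raise NetworkError("fixture networks support 1..20 nodes")
        lo, hi = self.indegree_range
        if not (1 <= lo <= hi):
            raise NetworkError("invalid in-degree range")
        if not 0.0 <= self.bias <= 1.0:
            raise NetworkError("bias must be a probability")


def _dnf_from_table(regulators: list, table: list) -> Expr:
    """Minterm expansion of a truth table (no simplification)."""
    k = len(regulators)
    ones = [i for i, v in enumerate(table) if v]
    if not ones:
        return Const(0)
    if len(ones) == 1 << k:
        return Const(1)
    terms = []
    for row in ones:
        lits = [
            Var(r) if (row >> j) & 1 else Not(Var(r))
            for j, r in enumerate(regulators)
        ]
        terms.append(lits[0] if len(lits) == 1 else And(lits))
    return terms[0] if len(terms) == 1 else Or(terms)


def generate_random_network(spec: RandomNetworkSpec) -> BooleanNetwork:
    """Deterministically generate a fixture network from the spec."""
    rng = random.Random(spec.seed)
    names = [f"n{i}" for i in range(spec.n)]
    lo, hi = spec.indegree_range
    pairs = []
    for name in names:
        k = min(rng.randint(lo, hi), spec.n)
        regulators = rng.sample(names, k)
        table = [1 if rng.random() < spec.bias else 0 for _ in range(1 << k)]
        pairs.append((name, _dnf_from_table(regulators, table)))
    return BooleanNetwork.from_rules(pairs)
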