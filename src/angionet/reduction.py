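"""Attractor-preserving network simplification operators.

Three operators mirror the standard logical-model reduction workflow:
removal of input nodes that are constant across all conditions of
interest, removal of output nodes (out-degree zero, influence nothing),
and edge contraction of intermediary relay nodes that are not protected
(in practice: not transcription factors).  Every operation is recorded in
a replayable log, so a reduced network is always reproducible from its
source.

Caveat inherited from the synchronous update scheme: inlining a rule into
its target changes the timing of cyclic attractors, so only fixed points
are guaranteed to survive contraction unchanged (projection onto the
surviving nodes); the other two operators preserve all attractors up to
projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .netcore import (
    And,
    BooleanNetwork,
    Const,
    Expr,
    NetworkError,
    Not,
    Or,
    Var,
    fold_constants,
)

__all__ = [
    "ReductionLog",
    "remove_constant_inputs",
    "remove_outputs",
    "contract_intermediaries",
    "replay",
]


@dataclass(frozen=True)
class ReductionOp:
    kind: str            # "removed_input" | "removed_output" | "contracted"
    node: str
    value: int | None = None      # fixed value for removed_input
    kept: str | None = None       # surviving node name for contracted
    polarity: int | None = None   # +1 / -1 for relay contraction


@dataclass
class ReductionLog:
    """Ordered record of applied reduction operations; replaying it on the
    original network reproduces the reduced network bit-exactly."""

    ops: list = field(default_factory=list)

    def append(self, op: ReductionOp):
        self.ops.append(op)

    def extend(self, other: "ReductionLog"):
        self.ops.extend(other.ops)

    def as_dicts(self) -> list:
        return [
            {k: v for k, v in op.__dict__.items() if v is not None} for op in self.ops
        ]


def _substitute(expr: Expr, name: str, replacement: Expr) -> Expr:
    t = type(expr)
    if t is Var:
        return replacement if expr.name == name else expr
    if t is Const:
        return expr
    if t is Not:
        child = _substitute(expr.child, name, replacement)
        if type(child) is Const:
            return Const(1 - child.value)
        return Not(child)
    children = [_substitute(c, name, replacement) for c in expr.children]
    folded = (And if t is And else Or)(children) if len(children) > 1 else children[0]
    return fold_constants(folded, {})


def remove_constant_inputs(
    net: BooleanNetwork, assignments: Mapping[str, int]
) -> tuple:
    """Delete input nodes fixed to a constant, substituting the constant
    into every rule (constant folding only)."""
    log = ReductionLog()
    for node, value in assignments.items():
        if node not in net.inputs:
            raise NetworkError(f"{node!r} is not a declared input node")
        if value not in (0, 1):
            raise NetworkError(f"fixed value for {node!r} must be 0 or 1")
    remaining = [n for n in net.nodes if n not in assignments]
    pairs = []
    for n in remaining:
        pairs.append((n, fold_constants(net.rules[n], dict(assignments))))
    for node, value in assignments.items():
        log.append(ReductionOp("removed_input", node, value=int(value)))
    inputs = tuple(n for n in net.inputs if n not in assignments)
    return BooleanNetwork.from_rules(pairs, inputs), log


def remove_outputs(net: BooleanNetwork) -> tuple:
    """Iteratively delete nodes referenced by no rule (out-degree zero).

    A self-loop counts as a reference, so inputs are never removed.  The
    attractors of the reduced network are the projections of the original
    attractors onto the surviving nodes.
    """
    log = ReductionLog()
    nodes = list(net.nodes)
    rules = dict(net.rules)
    while True:
        referenced = set()
        for n in nodes:
            referenced |= rules[n].variables()
        doomed = [n for n in nodes if n not in referenced]
        if not doomed:
            break
        for n in doomed:
            log.append(ReductionOp("removed_output", n))
            nodes.remove(n)
            del rules[n]
    inputs = tuple(n for n in net.inputs if n in set(nodes))
    return BooleanNetwork.from_rules([(n, rules[n]) for n in nodes], inputs), log


def _degrees(nodes: list, rules: Mapping[str, Expr]) -> tuple:
    indeg = {}
    outdeg = {n: 0 for n in nodes}
    targets = {n: [] for n in nodes}  # nodes whose rules reference n
    for n in nodes:
        refs = rules[n].variables()
        indeg[n] = len(refs)
        for r in refs:
            outdeg[r] += 1
            targets[r].append(n)
    return indeg, outdeg, targets


def contract_intermediaries(
    net: BooleanNetwork, protected: Iterable[str] = ()
) -> tuple:
    """Merge relay nodes (in- or out-degree one) into their neighbors.

    A node whose rule is a bare literal of its single regulator is replaced
    by that literal (with polarity) in all its targets; a node that feeds a
    single target has its rule inlined there.  Protected nodes (typically
    transcription factors), inputs, and self-regulating nodes are left
    alone, and no contraction may create a self-loop.  Applied repeatedly
    in node order until no eligible node remains.
    """
    protected = set(protected) | set(net.inputs)
    log = ReductionLog()
    nodes = list(net.nodes)
    rules = dict(net.rules)

    def eligible():
        indeg, outdeg, targets = _degrees(nodes, rules)
        for u in nodes:
            if u in protected:
                continue
            refs = rules[u].variables()
            if u in refs:  # self-regulating: lies on a 1-cycle, keep
                continue
            # relay of a single regulator: replace u by ±regulator downstream
            # (out-degree-0 nodes are outputs, not intermediaries)
            if indeg[u] == 1 and outdeg[u] >= 1 and type(rules[u]) in (Var, Not):
                expr = rules[u]
                polarity = 1 if type(expr) is Var else -1
                reg = expr.name if polarity == 1 else expr.child.name
                if reg in targets[u]:
                    continue  # reg -> u -> reg two-cycle: would self-loop
                return u, "relay", reg, polarity, targets[u]
            # feeds exactly one target: inline f_u into it
            if outdeg[u] == 1:
                target = targets[u][0]
                if target in rules[u].variables():
                    continue  # inlining would create a self-loop
                return u, "inline", target, None, [target]
        return None

    while (found := eligible()) is not None:
        u, kind, other, polarity, affected = found
        if kind == "relay":
            replacement: Expr = Var(other) if polarity == 1 else Not(Var(other))
            for t in affected:
                rules[t] = _substitute(rules[t], u, replacement)
            log.append(
                ReductionOp("contracted", u, kept=other, polarity=polarity)
            )
        else:
            rules[other] = _substitute(rules[other], u, rules[u])
            log.append(ReductionOp("contracted", u, kept=other, polarity=1))
        nodes.remove(u)
        del rules[u]
    inputs = tuple(n for n in net.inputs if n in set(nodes))
    return BooleanNetwork.from_rules([(n, rules[n]) for n in nodes], inputs), log


def replay(net: BooleanNetwork, log: ReductionLog) -> BooleanNetwork:
    """Re-apply a reduction log to the original network."""
    current = net
    fixed: dict = {}
    i = 0
    ops = log.ops
    while i < len(ops):
        op = ops[i]
        if op.kind == "removed_input":
            batch = {}
            while i < len(ops) and ops[i].kind == "removed_input":
                batch[ops[i].node] = ops[i].value
                i += 1
            current, _ = remove_constant_inputs(current, batch)
            fixed.update(batch)
            continue
        if op.kind == "removed_output":
            nodes = [n for n in current.nodes if n != op.node]
            rules = {n: current.rules[n] for n in nodes}
            inputs = tuple(n for n in current.inputs if n != op.node)
            current = BooleanNetwork.from_rules(
                [(n, rules[n]) for n in nodes], inputs
            )
        elif op.kind == "contracted":
            rules = dict(current.rules)
            replacement = rules[op.node]
            for n in current.nodes:
                if n == op.node:
                    continue
                rules[n] = _substitute(rules[n], op.node, replacement)
            nodes = [n for n in current.nodes if n != op.node]
            inputs = tuple(n for n in current.inputs if n != op.node)
            current = BooleanNetwork.from_rules(
                [(n, rules[n]) for n in nodes], inputs
            )
        i += 1
    return current
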