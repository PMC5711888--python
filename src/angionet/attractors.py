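"""Exact attractor computation for synchronous Boolean networks.

Three complementary paths are provided:

* trajectory iteration from a single start state (``iterate_to_attractor``),
* brute-force enumeration over all 2^n states for small networks
  (``enumerate_attractors_bruteforce``), which doubles as the verification
  oracle for everything else, and
* scalable exact enumeration for one fixed micro-environment
  (``enumerate_attractors_env``): clamp the inputs, propagate constants,
  condense the remaining dependency graph into strongly connected
  components and extend periodic orbits component by component through the
  condensation DAG.  The result is the complete attractor set of the
  clamped network — no sampling, no missed attractors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

from .netcore import (
    BooleanNetwork,
    Const,
    Expr,
    NetworkError,
    Var,
    evaluate,
    fold_constants,
    to_string,
)

__all__ = [
    "MicroEnvironment",
    "Attractor",
    "AttractorSet",
    "iterate_to_attractor",
    "enumerate_attractors_bruteforce",
    "clamp_inputs",
    "propagate_constants",
    "enumerate_attractors_env",
]

BRUTE_FORCE_CAP = 20  # default node cap for exhaustive 2^n enumeration


# ---------------------------------------------------------------------------
# Micro-environment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicroEnvironment:
    """Truth assignment over a network's declared input nodes.

    ``names`` is the documented input order; the integer ``code`` packs the
    values with the FIRST input as the most significant bit, so for the
    bundled model VEGFC_Dp is the MSB and AMPATP the LSB of a 0..65535 code.
    """

    names: tuple
    values: tuple

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise NetworkError("environment names/values length mismatch")
        if any(v not in (0, 1) for v in self.values):
            raise NetworkError("environment values must be 0 or 1")

    @property
    def assignment(self) -> dict:
        return dict(zip(self.names, self.values))

    @property
    def code(self) -> int:
        c = 0
        for v in self.values:
            c = (c << 1) | v
        return c

    @classmethod
    def from_code(cls, names: Sequence[str], code: int) -> "MicroEnvironment":
        names = tuple(names)
        k = len(names)
        if not 0 <= code < (1 << k):
            raise NetworkError(f"environment code {code} out of range for {k} inputs")
        values = tuple((code >> (k - 1 - i)) & 1 for i in range(k))
        return cls(names, values)

    @classmethod
    def from_assignment(cls, names: Sequence[str], assignment: Mapping[str, int]) -> "MicroEnvironment":
        names = tuple(names)
        missing = set(names) - set(assignment)
        extra = set(assignment) - set(names)
        if missing or extra:
            raise NetworkError(
                f"environment must cover exactly the declared inputs "
                f"(missing: {sorted(missing)}, unknown: {sorted(extra)})"
            )
        return cls(names, tuple(int(assignment[n]) for n in names))


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------

class Attractor:
    """A canonical cyclic state sequence closed under the update map.

    States are packed integers in the owning network's bit order; the
    canonical form is the rotation starting at the minimum state, which
    makes two discoveries of the same cycle compare and hash identically.
    """

    __slots__ = ("nodes", "states")

    def __init__(self, nodes: Sequence[str], states: Sequence[int]):
        states = list(states)
        if not states or len(set(states)) != len(states):
            raise NetworkError("attractor states must be nonempty and distinct")
        k = states.index(min(states))
        self.nodes = tuple(nodes)
        self.states = tuple(states[k:] + states[:k])

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def id(self) -> str:
        """Stable digest of the canonical rotation (cross-run identity)."""
        h = hashlib.sha256()
        h.update(",".join(self.nodes).encode())
        for s in self.states:
            h.update(s.to_bytes((len(self.nodes) + 7) // 8, "little"))
        return h.hexdigest()[:16]

    def state_bits(self) -> list:
        n = len(self.nodes)
        return ["".join(str((s >> i) & 1) for i in range(n)) for s in self.states]

    def values(self, name: str) -> tuple:
        i = self.nodes.index(name)
        return tuple((s >> i) & 1 for s in self.states)

    def __eq__(self, other):
        return (
            isinstance(other, Attractor)
            and other.nodes == self.nodes
            and other.states == self.states
        )

    def __hash__(self):
        return hash((self.nodes, self.states))

    def __repr__(self):
        kind = "fixed point" if self.is_fixed_point else f"{self.length}-cycle"
        return f"<Attractor {kind} id={self.id()}>"


@dataclass(frozen=True)
class AttractorSet:
    """The complete attractor set of a network (optionally tagged with the
    micro-environment it was enumerated under)."""

    attractors: frozenset
    environment: MicroEnvironment | None = None

    def __len__(self):
        return len(self.attractors)

    def __iter__(self):
        return iter(sorted(self.attractors, key=lambda a: a.states))

    @property
    def lengths(self) -> list:
        return sorted(a.length for a in self.attractors)


# ---------------------------------------------------------------------------
# Trajectory iteration
# ---------------------------------------------------------------------------

def iterate_to_attractor(net: BooleanNetwork, start: int) -> tuple:
    """Follow the trajectory from ``start`` until it cycles.

    Returns ``(attractor, transient_length)``.  Termination is guaranteed by
    the finite deterministic state space; detection uses a visited map, not
    a step cap.
    """
    step = net.step_function()
    seen = {start: 0}
    path = [start]
    s = start
    while True:
        s = step(s)
        if s in seen:
            k = seen[s]
            return Attractor(net.nodes, path[k:]), k
        seen[s] = len(path)
        path.append(s)


# ---------------------------------------------------------------------------
# Brute force (the oracle)
# ---------------------------------------------------------------------------

def enumerate_attractors_bruteforce(net: BooleanNetwork, cap: int = BRUTE_FORCE_CAP) -> AttractorSet:
    """Visit all 2^n states and return every attractor exactly once."""
    n = net.n
    if n > cap:
        raise NetworkError(f"brute-force enumeration capped at {cap} nodes (network has {n})")
    step = net.step_function()
    size = 1 << n
    color = bytearray(size)  # 0 unvisited, 1 on current path, 2 done
    attractors = []
    for s0 in range(size):
        if color[s0]:
            continue
        path = []
        s = s0
        while color[s] == 0:
            color[s] = 1
            path.append(s)
            s = step(s)
        if color[s] == 1:  # fresh cycle discovered on this walk
            k = path.index(s)
            attractors.append(Attractor(net.nodes, path[k:]))
        for t in path:
            color[t] = 2
    return AttractorSet(frozenset(attractors))


def basin_sizes(net: BooleanNetwork, cap: int = BRUTE_FORCE_CAP) -> dict:
    """Map each attractor to its basin size (brute force; toys only)."""
    n = net.n
    if n > cap:
        raise NetworkError(f"basin computation capped at {cap} nodes")
    step = net.step_function()
    attractors = {a: 0 for a in enumerate_attractors_bruteforce(net, cap).attractors}
    member = {}
    for a in attractors:
        for s in a.states:
            member[s] = a
    for s0 in range(1 << n):
        s = s0
        while s not in member:
            s = step(s)
        attractors[member[s]] += 1
    return attractors


# ---------------------------------------------------------------------------
# Clamping and sound constant propagation
# ---------------------------------------------------------------------------

def propagate_constants(net: BooleanNetwork, assignment: Mapping[str, int]) -> tuple:
    """Fix ``assignment`` and iteratively fold rules to constants.

    Returns ``(fixed, free_rules)`` where ``fixed`` maps node -> 0/1 for
    every node whose rule collapses to a constant given the clamp, and
    ``free_rules`` holds the folded rules of the remaining free nodes
    (referencing free nodes only).

    Soundness: a rule that folds to a constant c forces its node to c after
    one step regardless of history, so every recurrent (attractor) state
    satisfies all propagated constants; no free dynamics is ever
    contradicted.
    """
    fixed = {}
    for name, v in assignment.items():
        if name not in net._index:
            raise NetworkError(f"clamp names unknown node {name!r}")
        fixed[name] = int(v)
    dependents = net._cache.get("dependents")
    if dependents is None:
        dependents = {n: [] for n in net.nodes}
        for name in net.nodes:
            for ref in net.rules[name].variables():
                dependents[ref].append(name)
        net._cache["dependents"] = dependents

    free_rules = {}
    newly_fixed = list(fixed)
    for name in net.nodes:
        if name in fixed:
            continue
        e = fold_constants(net.rules[name], fixed)
        if type(e) is Const:
            fixed[name] = e.value
            newly_fixed.append(name)
        else:
            free_rules[name] = e
    while newly_fixed:
        name = newly_fixed.pop()
        for dep in dependents[name]:
            if dep not in free_rules:
                continue
            e = fold_constants(free_rules[dep], fixed)
            if type(e) is Const:
                del free_rules[dep]
                fixed[dep] = e.value
                newly_fixed.append(dep)
            else:
                free_rules[dep] = e
    return fixed, free_rules


def clamp_inputs(net: BooleanNetwork, env: MicroEnvironment) -> BooleanNetwork:
    """Clamp the declared inputs to ``env`` and propagate constants.

    The returned network has the same nodes in the same order; every node
    fixed by propagation carries a constant rule, all others carry their
    folded rule.
    """
    if tuple(env.names) != tuple(net.inputs):
        raise NetworkError("environment must cover exactly the declared inputs, in order")
    fixed, free_rules = propagate_constants(net, env.assignment)
    pairs = [
        (n, Const(fixed[n]) if n in fixed else free_rules[n])
        for n in net.nodes
    ]
    return BooleanNetwork.from_rules(pairs, inputs=net.inputs, strict=False)


# ---------------------------------------------------------------------------
# SCC-layered exact enumeration
# ---------------------------------------------------------------------------

def _condensation_order(names: Sequence[str], rules: Mapping[str, Expr]) -> list:
    """SCCs of the dependency graph (edge u->v if v's rule reads u), in
    topological order, regulators first.  Iterative Tarjan."""
    index = {n: i for i, n in enumerate(names)}
    succ = {n: [] for n in names}
    for v in names:
        for u in rules[v].variables():
            if u in index:
                succ[u].append(v)
    low = {}
    num = {}
    on_stack = set()
    stack = []
    sccs = []
    counter = [0]

    for root in names:
        if root in num:
            continue
        work = [(root, 0)]
        while work:
            v, pi = work[-1]
            if pi == 0:
                num[v] = low[v] = counter[0]
                counter[0] += 1
                stack.append(v)
                on_stack.add(v)
            recurse = False
            children = succ[v]
            while pi < len(children):
                w = children[pi]
                pi += 1
                if w not in num:
                    work[-1] = (v, pi)
                    work.append((w, 0))
                    recurse = True
                    break
                if w in on_stack:
                    low[v] = min(low[v], num[w])
            if recurse:
                continue
            work[-1] = (v, pi)
            if low[v] == num[v]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.append(w)
                    if w == v:
                        break
                sccs.append(sorted(comp, key=index.get))
            work.pop()
            if work:
                p = work[-1][0]
                low[p] = min(low[p], low[v])
    sccs.reverse()  # Tarjan emits sinks first; we want regulators first
    return sccs


def enumerate_core_orbits(names: Sequence[str], rules: Mapping[str, Expr]) -> list:
    """All attractors of the free core, as lists of assignment dicts.

    Periodic orbits are built bottom-up through the condensation DAG: for
    each upstream orbit of period p and each downstream SCC with m nodes,
    the p-step return map over the 2^m component states is a deterministic
    function whose cycles are in one-to-one correspondence with the
    attractors of the extended prefix.
    """
    if not names:
        return [[{}]]
    orbits = [[{}]]
    for scc in _condensation_order(names, rules):
        m = len(scc)
        scc_rules = [rules[n] for n in scc]
        extended = []
        for orbit in orbits:
            p = len(orbit)
            ret_map = {}
            for sval in product((0, 1), repeat=m):
                cur = sval
                for t in range(p):
                    a = dict(orbit[t])
                    a.update(zip(scc, cur))
                    cur = tuple(evaluate(r, a) for r in scc_rules)
                ret_map[sval] = cur
            done = set()
            for s0 in ret_map:
                if s0 in done:
                    continue
                path = []
                pos = {}
                s = s0
                while s not in done and s not in pos:
                    pos[s] = len(path)
                    path.append(s)
                    s = ret_map[s]
                if s in pos:  # fresh cycle of the return map
                    cyc = path[pos[s]:]
                    start = min(cyc)
                    full = []
                    cur = start
                    t = 0
                    while True:
                        a = dict(orbit[t % p])
                        a.update(zip(scc, cur))
                        full.append(a)
                        cur = tuple(evaluate(r, a) for r in scc_rules)
                        t += 1
                        if t % p == 0 and cur == start:
                            break
                    extended.append(full)
                done.update(path)
        orbits = extended
    return orbits


#: layered brute force handles SCCs up to this many nodes; larger cores go
#: to the symbolic (BDD) recurrent-set backend
SCC_BRUTE_CAP = 13

#: completeness guard for the symbolic backend (recurrent states per core)
RECURRENT_STATE_CAP = 200_000


def _regulators_last_order(names: Sequence[str], rules: Mapping[str, Expr]) -> list:
    """Variable order for the symbolic backend: reversed DFS post-order of
    the dependency graph, so each node sits above its regulators.  This
    keeps the decision diagrams of signaling cascades compact."""
    nameset = set(names)
    seen: set = set()
    order: list = []

    def visit(v):
        stack = [(v, None)]
        while stack:
            node, it = stack.pop()
            if it is None:
                if node in seen:
                    continue
                seen.add(node)
                it = iter(sorted(rules[node].variables()))
            advanced = False
            for u in it:
                if u in nameset and u not in seen:
                    stack.append((node, it))
                    stack.append((u, None))
                    advanced = True
                    break
            if not advanced:
                order.append(node)

    for v in names:
        visit(v)
    return list(reversed(order))


#: candidate attractors are first harvested from this many trajectories
#: before the completeness proof starts; the result does not depend on it
_PRESIM_TRAJECTORIES = 96


def _core_orbits_bdd(names: Sequence[str], rules: Mapping[str, Expr]) -> list:
    """Exact core attractors via simulation certified by backward closure.

    Candidate attractors are found by plain trajectory iteration with the
    compiled core update map; completeness is then certified symbolically:
    the set of states that never reach a known attractor is computed as a
    greatest fixpoint under the preimage operator (BDD vector composition).
    If it is empty, every state of the core provably reaches an enumerated
    attractor; otherwise any member is a counterexample whose trajectory
    yields a new attractor.  Exact — no sampling in the certificate.

    Uses the numba-jitted manager when available (with mark-and-rebuild
    garbage collection on node-pool overflow), the pure-Python one when
    numba is not importable.
    """
    try:
        from .bdd import KernelBDD as manager_cls
        manager_cls([])  # force kernel import before committing to it
    except ImportError:
        from .bdd import BDD as manager_cls
    return _core_orbits_bdd_with(names, rules, manager_cls)


def _core_orbits_bdd_with(names, rules, manager_cls) -> list:
    import random as _random

    from .bdd import FALSE, TRUE

    core = BooleanNetwork.from_rules([(n, rules[n]) for n in names])
    step = core.step_function()
    mgr = manager_cls(_regulators_last_order(names, rules))

    def cycle_from(s0: int) -> list:
        seen = {}
        path = []
        s = s0
        while s not in seen:
            seen[s] = len(path)
            path.append(s)
            s = step(s)
        return path[seen[s]:]

    rng = _random.Random(0x5EED)  # candidate harvest only; outcome-independent
    orbits_packed: list = []
    state = {"funcs": None, "avoid": TRUE}

    def guarded(operation):
        """Run one BDD step; on pool overflow collect garbage and retry."""
        for attempt in (0, 1):
            try:
                return operation()
            except MemoryError:
                if attempt or not hasattr(mgr, "collect"):
                    raise NetworkError(
                        "exact enumeration infeasible: symbolic certificate "
                        "exceeds the node pool even after garbage collection"
                    )
                roots = mgr.collect([state["avoid"], *state["funcs"]])
                state["avoid"] = roots[0]
                state["funcs"] = tuple(roots[1:])

    # rule BDDs are small; an overflow here would be a genuine failure
    state["funcs"] = tuple(mgr.from_expr(rules[v]) for v in mgr.variables)
    starts = [0] + [rng.getrandbits(len(names)) for _ in range(_PRESIM_TRAJECTORIES)]
    while True:
        for s0 in starts:
            cyc = cycle_from(s0)
            mn = min(cyc)
            if all(min(o) != mn for o in orbits_packed):
                orbits_packed.append(cyc)
                for s in cyc:
                    state["avoid"] = guarded(
                        lambda s=s: mgr.apply_and(
                            state["avoid"],
                            mgr.apply_not(mgr.point(core.unpack_state(s))),
                        )
                    )
        while True:  # greatest fixpoint: states whose whole orbit avoids them
            narrowed = guarded(
                lambda: mgr.apply_and(
                    state["avoid"], mgr.compose(state["avoid"], state["funcs"])
                )
            )
            if narrowed == state["avoid"]:
                break
            state["avoid"] = narrowed
        if state["avoid"] == FALSE:
            break
        starts = [core.pack_state(next(mgr.iter_assignments(state["avoid"])))]
    return [[core.unpack_state(s) for s in cyc] for cyc in orbits_packed]


#: whole-core explicit enumeration is used up to this many free nodes
POINTER_DOUBLING_CAP = 20


def _core_orbits_pointer(names: Sequence[str], rules: Mapping[str, Expr]) -> list:
    """Exact core attractors by explicit functional-graph pointer doubling.

    Builds the full successor table over the 2^k core states with the
    bit-parallel step, then squares the map k times; the resulting image is
    exactly the set of recurrent states, which is partitioned into cycles
    by direct walking.  Memory-bound at ``POINTER_DOUBLING_CAP`` bits.
    """
    import numpy as np

    core = BooleanNetwork.from_rules([(n, rules[n]) for n in names])
    step = core.step_function()
    k = len(names)
    size = 1 << k
    succ = np.empty(size, dtype=np.uint32)
    chunk = 1 << 22
    for lo in range(0, size, chunk):
        block = np.arange(lo, min(lo + chunk, size), dtype=np.uint64)
        succ[lo : lo + block.shape[0]] = step(block).astype(np.uint32)
    reach = succ
    for _ in range(k):  # f^(2^k) with 2^k >= any transient length
        reach = reach[reach]
    recurrent = np.unique(reach)
    remaining = set(int(s) for s in recurrent)
    orbits = []
    while remaining:
        s0 = min(remaining)
        cyc = [s0]
        s = int(succ[s0])
        while s != s0:
            cyc.append(s)
            s = int(succ[s])
        remaining.difference_update(cyc)
        orbits.append([core.unpack_state(s) for s in cyc])
    return orbits


def core_orbits(names: Sequence[str], rules: Mapping[str, Expr], backend: str = "auto") -> list:
    """Attractors of a free core as orbits (lists of assignment dicts).

    ``backend`` is ``"scc"`` (layered brute force through the condensation),
    ``"bdd"`` (symbolic recurrent set), or ``"auto"`` which uses the layered
    path when every strongly connected component is small enough to
    enumerate directly and the symbolic path otherwise.  Both are exact.
    """
    if not names:
        return [[{}]]
    if backend == "scc":
        return enumerate_core_orbits(names, rules)
    if backend == "bdd":
        return _core_orbits_bdd(names, rules)
    if backend == "pointer":
        return _core_orbits_pointer(names, rules)
    if backend == "brute":
        core = BooleanNetwork.from_rules([(n, rules[n]) for n in names])
        return [
            [core.unpack_state(s) for s in a.states]
            for a in enumerate_attractors_bruteforce(core)
        ]
    if backend != "auto":
        raise NetworkError(f"unknown backend {backend!r}")
    sccs = _condensation_order(names, rules)
    if max(len(s) for s in sccs) <= SCC_BRUTE_CAP:
        return enumerate_core_orbits(names, rules)
    if len(names) <= POINTER_DOUBLING_CAP:
        return _core_orbits_pointer(names, rules)
    return _core_orbits_bdd(names, rules)


def enumerate_attractors_env(
    net: BooleanNetwork, env: MicroEnvironment, backend: str = "auto"
) -> AttractorSet:
    """Exact attractor set of ``net`` under a fixed micro-environment.

    Attractor states are re-embedded in full n-node packed states with the
    clamped input (and propagated constant) bits filled in.
    """
    if tuple(env.names) != tuple(net.inputs):
        raise NetworkError("environment must cover exactly the declared inputs, in order")
    fixed, free_rules = propagate_constants(net, env.assignment)
    free = [n for n in net.nodes if n in free_rules]
    orbits = core_orbits(free, free_rules, backend)
    base = 0
    for name, v in fixed.items():
        if v:
            base |= 1 << net._index[name]
    attractors = []
    for orbit in orbits:
        states = []
        for a in orbit:
            s = base
            for name, v in a.items():
                if v:
                    s |= 1 << net._index[name]
            states.append(s)
        attractors.append(Attractor(net.nodes, states))
    return AttractorSet(frozenset(attractors), environment=env)
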