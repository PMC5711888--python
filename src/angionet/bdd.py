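"""A compact reduced-ordered-BDD engine for exact symbolic analysis.

Purpose-built for attractor search in clamped Boolean networks: build the
update functions as BDDs, iterate the forward image of the full state space
until it reaches a fixpoint (the set of recurrent states of a deterministic
map), then enumerate that — typically tiny — set explicitly.

Nodes are integers; 0 and 1 are the terminals.  Non-terminals live in
``self._nodes`` as ``(level, lo, hi)`` triples with a unique table, so
structural equality is pointer equality.  The image operator uses input
cofactoring (case split on the top state variable, memoized on the
function-vector identity), which avoids building a monolithic transition
relation and behaves well on the sparse, shallow rules found in signaling
network models.
"""

from __future__ import annotations

from .netcore import And, Const, Expr, Not, Or, Var

FALSE = 0
TRUE = 1


class BDD:
    """A BDD manager over a fixed ordered variable list."""

    def __init__(self, variables):
        self.variables = list(variables)
        self.level = {v: i for i, v in enumerate(self.variables)}
        self._nodes = [None, None]  # id -> (level, lo, hi)
        self._unique = {}
        self._ite_memo = {}
        self._img_memo = {}
        self._img_funcs = None
        self._compose_memo = {}
        self._compose_funcs = None

    # -- construction ------------------------------------------------------
    def _mk(self, level: int, lo: int, hi: int) -> int:
        if lo == hi:
            return lo
        key = (level, lo, hi)
        node = self._unique.get(key)
        if node is None:
            node = len(self._nodes)
            self._nodes.append(key)
            self._unique[key] = node
        return node

    def var(self, name: str) -> int:
        return self._mk(self.level[name], FALSE, TRUE)

    def _top(self, *fs) -> int:
        return min(self._nodes[f][0] for f in fs if f > 1)

    def _cof(self, f: int, level: int):
        if f <= 1:
            return f, f
        l, lo, hi = self._nodes[f]
        if l == level:
            return lo, hi
        return f, f

    def ite(self, f: int, g: int, h: int) -> int:
        if f == TRUE:
            return g
        if f == FALSE:
            return h
        if g == h:
            return g
        if g == TRUE and h == FALSE:
            return f
        key = (f, g, h)
        r = self._ite_memo.get(key)
        if r is not None:
            return r
        level = self._top(f, g, h)
        f0, f1 = self._cof(f, level)
        g0, g1 = self._cof(g, level)
        h0, h1 = self._cof(h, level)
        r = self._mk(level, self.ite(f0, g0, h0), self.ite(f1, g1, h1))
        self._ite_memo[key] = r
        return r

    def apply_and(self, f: int, g: int) -> int:
        return self.ite(f, g, FALSE)

    def apply_or(self, f: int, g: int) -> int:
        return self.ite(f, TRUE, g)

    def apply_not(self, f: int) -> int:
        return self.ite(f, FALSE, TRUE)

    def from_expr(self, expr: Expr) -> int:
        t = type(expr)
        if t is Var:
            return self.var(expr.name)
        if t is Const:
            return TRUE if expr.value else FALSE
        if t is Not:
            return self.apply_not(self.from_expr(expr.child))
        if t is And:
            r = TRUE
            for c in expr.children:
                r = self.apply_and(r, self.from_expr(c))
            return r
        if t is Or:
            r = FALSE
            for c in expr.children:
                r = self.apply_or(r, self.from_expr(c))
            return r
        raise TypeError(f"unsupported expression node {t}")

    # -- deterministic-map image -------------------------------------------
    def image(self, s: int, funcs: tuple) -> int:
        """Set of successors of ``s`` under the vector function ``funcs``.

        ``funcs[i]`` is the BDD of the update rule for variable i (one per
        manager variable, in manager order); the result is a BDD over the
        same variables.  The recursion splits the source set on each output
        in turn — states mapped to ``var_i = 0`` versus ``var_i = 1`` —
        and is memoized on the (source set, output index) pair, which keeps
        repeated image computations against the same ``funcs`` cheap.
        """
        if funcs is not self._img_funcs:
            self._img_memo.clear()
            self._img_funcs = funcs
        n = len(funcs)
        memo = self._img_memo

        def rec(src: int, i: int) -> int:
            if src == FALSE:
                return FALSE
            if i == n:
                return TRUE
            key = (src, i)
            r = memo.get(key)
            if r is None:
                f = funcs[i]
                r0 = rec(self.ite(f, FALSE, src), i + 1)  # src ∧ ¬f
                r1 = rec(self.ite(f, src, FALSE), i + 1)  # src ∧ f
                r = self._mk(i, r0, r1)
                memo[key] = r
            return r

        return rec(s, 0)

    # -- preimage via vector composition ------------------------------------
    def compose(self, u: int, funcs: tuple) -> int:
        """Substitute ``funcs`` for the variables of ``u`` (Shannon expansion).

        For a deterministic update map f this is exactly the preimage
        operator: ``compose(S, f)(x) = S(f(x))``, i.e. the set of states
        whose successor lies in S.  Memoized per (node, function vector).
        """
        if funcs is not self._compose_funcs:
            self._compose_memo.clear()
            self._compose_funcs = funcs
        memo = self._compose_memo

        def rec(node: int) -> int:
            if node <= 1:
                return node
            r = memo.get(node)
            if r is None:
                level, lo, hi = self._nodes[node]
                r = self.ite(funcs[level], rec(hi), rec(lo))
                memo[node] = r
            return r

        return rec(u)

    def point(self, assignment) -> int:
        """BDD of a single full assignment {var: 0/1}."""
        r = TRUE
        for name in reversed(self.variables):
            lvl = self.level[name]
            r = self._mk(lvl, FALSE, r) if assignment[name] else self._mk(lvl, r, FALSE)
        return r

    # -- inspection --------------------------------------------------------
    def count(self, f: int) -> int:
        """Number of satisfying assignments over the full variable list."""
        n = len(self.variables)
        memo = {}

        def lev(node: int) -> int:
            return n if node <= 1 else self._nodes[node][0]

        def sc(node: int) -> int:
            if node == FALSE:
                return 0
            if node == TRUE:
                return 1
            r = memo.get(node)
            if r is not None:
                return r
            level, lo, hi = self._nodes[node]
            r = (sc(lo) << (lev(lo) - level - 1)) + (sc(hi) << (lev(hi) - level - 1))
            memo[node] = r
            return r

        return sc(f) << lev(f)

    def iter_assignments(self, f: int):
        """Yield satisfying assignments as dicts over the full variable list."""
        n = len(self.variables)

        def rec(node: int, level: int, partial: dict):
            if node == FALSE:
                return
            if level == n:
                yield dict(partial)
                return
            name = self.variables[level]
            if node > 1 and self._nodes[node][0] == level:
                _, lo, hi = self._nodes[node]
                for val, child in ((0, lo), (1, hi)):
                    partial[name] = val
                    yield from rec(child, level + 1, partial)
                del partial[name]
            else:
                for val in (0, 1):
                    partial[name] = val
                    yield from rec(node, level + 1, partial)
                del partial[name]

        yield from rec(f, 0, {})


class KernelBDD:
    """Accelerated manager backed by the numba kernel in ``_bddkern``.

    API-compatible with :class:`BDD` for the operations the attractor
    backend needs.  All managers in a process share one set of kernel
    arrays; constructing a manager bumps the kernel epoch, which
    invalidates previous nodes and caches in O(1).  Within one epoch
    ``compose`` must always be called with the same function vector (the
    compose cache is keyed per epoch) — the attractor backend's usage.
    """

    _state = None

    def __init__(self, variables):
        from . import _bddkern as K

        if len(variables) >= K.TERMINAL_LEVEL:
            raise ValueError("too many variables for the kernel manager")
        if KernelBDD._state is None:
            KernelBDD._state = K.new_state()
        K.next_epoch(KernelBDD._state)
        self._K = K
        s = KernelBDD._state
        self._mk_args = (s[0], s[1], s[2], s[3], s[4], s[10])
        self._ite_args = s[0:8] + (s[10], s[11], s[12])
        self._comp_args = s[0:8] + s[8:15]
        self._lvl, self._lo, self._hi = s[0], s[1], s[2]
        self.variables = list(variables)
        self.level = {v: i for i, v in enumerate(self.variables)}
        self._funcs_cache = {}

    # -- construction ------------------------------------------------------
    def _mk(self, level: int, lo: int, hi: int) -> int:
        import numpy as np

        return int(self._K._mk(np.int64(level), np.int64(lo), np.int64(hi), *self._mk_args))

    def var(self, name: str) -> int:
        return self._mk(self.level[name], 0, 1)

    def ite(self, f: int, g: int, h: int) -> int:
        import numpy as np

        return int(self._K._ite(np.int64(f), np.int64(g), np.int64(h), *self._ite_args))

    def apply_and(self, f: int, g: int) -> int:
        return self.ite(f, g, FALSE)

    def apply_or(self, f: int, g: int) -> int:
        return self.ite(f, TRUE, g)

    def apply_not(self, f: int) -> int:
        return self.ite(f, FALSE, TRUE)

    from_expr = BDD.from_expr
    point = BDD.point

    # -- preimage ----------------------------------------------------------
    def compose(self, u: int, funcs: tuple) -> int:
        import numpy as np

        arr = self._funcs_cache.get(funcs)
        if arr is None:
            arr = np.asarray(funcs, dtype=np.int64)
            self._funcs_cache[funcs] = arr
        return int(self._K._compose(np.int64(u), arr, *self._comp_args))

    # -- garbage collection ------------------------------------------------
    def collect(self, roots):
        """Rebuild only the nodes reachable from ``roots`` in a fresh epoch.

        Called when the kernel's node pool overflows: everything else is
        operator garbage.  Returns the remapped root ids; all previous node
        ids (and cached function vectors) become invalid.
        """
        s = KernelBDD._state
        used = int(s[10][0])
        lvl_old = s[0][:used].copy()
        lo_old = s[1][:used].copy()
        hi_old = s[2][:used].copy()
        self._K.next_epoch(s)
        self._funcs_cache.clear()
        memo = {0: 0, 1: 1}

        def build(u: int) -> int:
            if u in memo:
                return memo[u]
            stack = [u]
            while stack:
                v = stack[-1]
                if v in memo:
                    stack.pop()
                    continue
                l, h = int(lo_old[v]), int(hi_old[v])
                if l in memo and h in memo:
                    memo[v] = self._mk(int(lvl_old[v]), memo[l], memo[h])
                    stack.pop()
                else:
                    if l not in memo:
                        stack.append(l)
                    if h not in memo:
                        stack.append(h)
            return memo[u]

        return [build(int(r)) for r in roots]

    # -- inspection --------------------------------------------------------
    def _node(self, node: int):
        return (int(self._lvl[node]), int(self._lo[node]), int(self._hi[node]))

    def iter_assignments(self, f: int):
        n = len(self.variables)

        def rec(node, level, partial):
            if node == FALSE:
                return
            if level == n:
                yield dict(partial)
                return
            name = self.variables[level]
            if node > 1 and self._lvl[node] == level:
                _, lo, hi = self._node(node)
                for val, child in ((0, lo), (1, hi)):
                    partial[name] = val
                    yield from rec(child, level + 1, partial)
                del partial[name]
            else:
                for val in (0, 1):
                    partial[name] = val
                    yield from rec(node, level + 1, partial)
                del partial[name]

        yield from rec(f, 0, {})


def recurrent_states(variables, rules, max_states: int | None = None):
    """Exact set of recurrent states of a deterministic Boolean map.

    ``rules`` maps variable name -> Expr over ``variables``.  Iterates the
    forward image of the whole state space until it stops shrinking (the
    limit set of a deterministic map is exactly the union of its cycles)
    and returns the assignments as a list of dicts.

    Raises ``RuntimeError`` if the recurrent set exceeds ``max_states`` —
    the complete enumeration is then declared infeasible rather than
    silently truncated.
    """
    mgr = BDD(variables)
    funcs = tuple(mgr.from_expr(rules[v]) for v in mgr.variables)
    s = TRUE
    while True:
        s_next = mgr.image(s, funcs)
        if s_next == s:
            break
        s = s_next
    if max_states is not None and mgr.count(s) > max_states:
        raise RuntimeError(
            f"recurrent set has {mgr.count(s)} states, above the cap {max_states}"
        )
    return list(mgr.iter_assignments(s))
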