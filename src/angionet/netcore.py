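"""Boolean expression trees, network container, BoolNet-dialect text I/O,
and the synchronous update map.

A network is a function f : B^n -> B^n over an ordered list of named nodes.
States are packed integers: bit ``i`` holds the value of node ``i`` in file
order, which makes states hashable, orderable and cheap to copy.  Input
nodes (the micro-environment) are modeled as self-activating constants,
i.e. their update rule is the identity on themselves.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "Expr",
    "NetworkError",
    "ParseError",
    "BooleanNetwork",
    "parse_expression",
    "parse_network",
    "write_network",
    "evaluate",
    "fold_constants",
    "synchronous_step",
]


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

class Expr:
    """Base class for Boolean expression nodes (structural equality)."""

    __slots__ = ()

    def variables(self) -> frozenset:
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({to_string(self)!r})"


class Const(Expr):
    __slots__ = ("value",)

    def __init__(self, value: int):
        if value not in (0, 1):
            raise ValueError("constant must be 0 or 1")
        self.value = int(value)

    def variables(self):
        return frozenset()

    def __eq__(self, other):
        return isinstance(other, Const) and other.value == self.value

    def __hash__(self):
        return hash(("c", self.value))


class Var(Expr):
    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def variables(self):
        return frozenset((self.name,))

    def __eq__(self, other):
        return isinstance(other, Var) and other.name == self.name

    def __hash__(self):
        return hash(("v", self.name))


class Not(Expr):
    __slots__ = ("child",)

    def __init__(self, child: Expr):
        self.child = child

    def variables(self):
        return self.child.variables()

    def __eq__(self, other):
        return isinstance(other, Not) and other.child == self.child

    def __hash__(self):
        return hash(("n", self.child))


class _Nary(Expr):
    __slots__ = ("children",)

    def __init__(self, children: Iterable[Expr]):
        # Same-operator children are flattened so that serialization is a
        # fixpoint under reparsing; source order is preserved and nothing
        # else is simplified.
        flat = []
        for c in children:
            if type(c) is type(self):
                flat.extend(c.children)
            else:
                flat.append(c)
        if len(flat) < 2:
            raise ValueError("n-ary operator needs at least two children")
        self.children = tuple(flat)

    def variables(self):
        out = frozenset()
        for c in self.children:
            out |= c.variables()
        return out

    def __eq__(self, other):
        return type(other) is type(self) and other.children == self.children

    def __hash__(self):
        return hash((type(self).__name__, self.children))


class And(_Nary):
    __slots__ = ()


class Or(_Nary):
    __slots__ = ()


def evaluate(expr: Expr, assignment: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a total truth assignment (standard semantics)."""
    t = type(expr)
    if t is Var:
        try:
            return 1 if assignment[expr.name] else 0
        except KeyError:
            raise NetworkError(f"unassigned node reference: {expr.name!r}") from None
    if t is Const:
        return expr.value
    if t is Not:
        return 1 - evaluate(expr.child, assignment)
    if t is And:
        for c in expr.children:
            if not evaluate(c, assignment):
                return 0
        return 1
    # Or
    for c in expr.children:
        if evaluate(c, assignment):
            return 1
    return 0


def fold_constants(expr: Expr, fixed: Mapping[str, int]) -> Expr:
    """Partially evaluate ``expr`` substituting known constants.

    Only constant folding is performed (0 annihilates AND, 1 annihilates OR,
    neutral elements are dropped); no other algebraic rewriting, so the
    result stays textually traceable to its source rule.
    """
    t = type(expr)
    if t is Var:
        v = fixed.get(expr.name)
        return expr if v is None else Const(v)
    if t is Const:
        return expr
    if t is Not:
        c = fold_constants(expr.child, fixed)
        if type(c) is Const:
            return Const(1 - c.value)
        return Not(c)
    keep = []
    if t is And:
        for c in expr.children:
            fc = fold_constants(c, fixed)
            if type(fc) is Const:
                if fc.value == 0:
                    return Const(0)
                continue
            keep.append(fc)
        if not keep:
            return Const(1)
        return keep[0] if len(keep) == 1 else And(keep)
    # Or
    for c in expr.children:
        fc = fold_constants(c, fixed)
        if type(fc) is Const:
            if fc.value == 1:
                return Const(1)
            continue
        keep.append(fc)
    if not keep:
        return Const(0)
    return keep[0] if len(keep) == 1 else Or(keep)


# precedence levels for precedence-safe serialization
_PREC = {Or: 1, And: 2, Not: 3, Var: 4, Const: 4}


def to_string(expr: Expr) -> str:
    """Serialize with BoolNet operators; parentheses only where precedence requires."""

    def render(e: Expr, parent_prec: int) -> str:
        t = type(e)
        if t is Var:
            return e.name
        if t is Const:
            return str(e.value)
        if t is Not:
            return "!" + render(e.child, _PREC[Not])
        op = " & " if t is And else " | "
        body = op.join(render(c, _PREC[t]) for c in e.children)
        return f"({body})" if _PREC[t] < parent_prec else body

    return render(expr, 0)


# ---------------------------------------------------------------------------
# Parsing (header `targets, factors`; operators ! & |; comments with #)
# ---------------------------------------------------------------------------

class NetworkError(ValueError):
    """Semantic error in a Boolean network definition."""


class ParseError(NetworkError):
    """Syntax error in BoolNet-dialect text (carries a line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<lit>[01])|(?P<op>[!&|()]))")
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _tokenize(text: str, line: int):
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos:].strip()[0]!r} in expression", line)
        pos = m.end()
        if m.group("name"):
            tokens.append(("name", m.group("name")))
        elif m.group("lit"):
            tokens.append(("lit", int(m.group("lit"))))
        else:
            tokens.append(("op", m.group("op")))
    tokens.append(("end", None))
    return tokens


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse one Boolean expression with precedence NOT > AND > OR."""
    tokens = _tokenize(text, line)
    pos = 0

    def peek():
        return tokens[pos]

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def atom() -> Expr:
        kind, val = take()
        if kind == "name":
            return Var(val)
        if kind == "lit":
            return Const(val)
        if kind == "op" and val == "!":
            return Not(atom())
        if kind == "op" and val == "(":
            e = or_expr()
            kind, val = take()
            if not (kind == "op" and val == ")"):
                raise ParseError("expected ')'", line)
            return e
        raise ParseError(f"unexpected token {val!r}", line)

    def and_expr() -> Expr:
        terms = [atom()]
        while peek() == ("op", "&"):
            take()
            terms.append(atom())
        return terms[0] if len(terms) == 1 else And(terms)

    def or_expr() -> Expr:
        terms = [and_expr()]
        while peek() == ("op", "|"):
            take()
            terms.append(and_expr())
        return terms[0] if len(terms) == 1 else Or(terms)

    e = or_expr()
    if peek()[0] != "end":
        raise ParseError(f"trailing tokens after expression: {peek()[1]!r}", line)
    return e


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous Boolean network: ordered nodes, one update rule each.

    ``nodes`` order defines the packed-state bit order (bit i = node i) and
    is used everywhere states, canonical attractor forms, and reports are
    rendered.  ``inputs`` flags the micro-environment nodes, whose rules
    must be the identity self-loop unless ``strict=False`` at construction.
    """

    nodes: tuple
    rules: dict
    inputs: tuple = ()
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.nodes)})
        object.__setattr__(self, "_cache", {})

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, name: str) -> int:
        return self._index[name]

    # -- construction -----------------------------------------------------
    @staticmethod
    def from_rules(pairs: Sequence, inputs: Iterable[str] = (), strict: bool = True) -> "BooleanNetwork":
        """Build and validate a network from ``(name, Expr)`` pairs in order."""
        nodes = tuple(name for name, _ in pairs)
        if len(set(nodes)) != len(nodes):
            dup = sorted({n for n in nodes if sum(m == n for m in nodes) > 1})
            raise NetworkError(f"duplicate target node(s): {', '.join(dup)}")
        for n in nodes:
            if not _NAME_RE.match(n):
                raise NetworkError(f"invalid node name {n!r}")
        rules = dict(pairs)
        declared = set(nodes)
        for name, expr in rules.items():
            missing = expr.variables() - declared
            if missing:
                raise NetworkError(
                    f"rule for {name!r} references undeclared node(s): {', '.join(sorted(missing))}"
                )
        inputs = tuple(inputs)
        for inp in inputs:
            if inp not in declared:
                raise NetworkError(f"declared input {inp!r} is not a node")
            if strict and rules[inp] != Var(inp):
                raise NetworkError(
                    f"input node {inp!r} must have the identity self-loop rule "
                    f"(got {to_string(rules[inp])!r}); pass strict=False to allow"
                )
        return BooleanNetwork(nodes=nodes, rules=rules, inputs=inputs)

    def replace_rule(self, name: str, expr: Expr) -> "BooleanNetwork":
        """Return a copy with one rule replaced (validation relaxed for inputs)."""
        if name not in self._index:
            raise NetworkError(f"unknown node {name!r}")
        pairs = [(n, expr if n == name else self.rules[n]) for n in self.nodes]
        return BooleanNetwork.from_rules(pairs, self.inputs, strict=False)

    # -- packed-state helpers ---------------------------------------------
    def pack_state(self, assignment: Mapping[str, int]) -> int:
        """Pack a node -> {0,1} mapping into an integer state (bit i = node i)."""
        s = 0
        for name, i in self._index.items():
            v = assignment[name]
            if v not in (0, 1, True, False):
                raise NetworkError(f"state value for {name!r} must be 0 or 1")
            if v:
                s |= 1 << i
        return s

    def unpack_state(self, state: int) -> dict:
        return {name: (state >> i) & 1 for name, i in self._index.items()}

    def state_bits(self, state: int) -> str:
        """Render a packed state as a 0/1 string in node order."""
        return "".join(str((state >> i) & 1) for i in range(self.n))

    def state_from_bits(self, bits: str) -> int:
        bits = bits.strip()
        if len(bits) != self.n or set(bits) - {"0", "1"}:
            raise NetworkError(f"expected a {self.n}-character 0/1 string")
        return sum((bits[i] == "1") << i for i in range(self.n))

    # -- compiled update map ----------------------------------------------
    def step_function(self) -> Callable:
        """Compiled synchronous update map on packed states.

        The generated function works unchanged on Python ints and on numpy
        uint64 arrays (bit-parallel over many states at once); every
        component is computed from the same frozen pre-state.
        """
        cached = self._cache.get("step")
        if cached is not None:
            return cached
        lines = ["def _step(s):"]
        used = set()
        for expr in self.rules.values():
            used |= expr.variables()
        for name in sorted(used):
            i = self._index[name]
            lines.append(f"    x{i} = (s >> {i}) & 1")
        for i, name in enumerate(self.nodes):
            lines.append(f"    y{i} = {self._expr_code(self.rules[name])}")
        terms = " | ".join(f"(y{i} << {i})" for i in range(self.n))
        lines.append(f"    return {terms}")
        ns: dict = {}
        exec("\n".join(lines), ns)
        fn = ns["_step"]
        self._cache["step"] = fn
        return fn

    def _expr_code(self, expr: Expr) -> str:
        t = type(expr)
        if t is Var:
            return f"x{self._index[expr.name]}"
        if t is Const:
            return str(expr.value)
        if t is Not:
            return f"(1 - {self._expr_code(expr.child)})"
        op = " & " if t is And else " | "
        return "(" + op.join(self._expr_code(c) for c in expr.children) + ")"

    def digest(self) -> str:
        """Stable content hash of the network (nodes, rules, inputs)."""
        payload = write_network(self) + "\n#inputs: " + ",".join(self.inputs)
        return hashlib.sha256(payload.encode()).hexdigest()


def synchronous_step(net: BooleanNetwork, state: int) -> int:
    """One synchronous update: every node evaluated on the frozen pre-state."""
    return net.step_function()(state)


# ---------------------------------------------------------------------------
# BoolNet-dialect document I/O
# ---------------------------------------------------------------------------

def parse_network(text: str, input_names: Iterable[str] = (), strict: bool = True) -> BooleanNetwork:
    """Parse a ``targets, factors`` document into a :class:`BooleanNetwork`.

    One rule line per node, ``NAME, EXPR`` with ``!``/``&``/``|`` and
    parentheses; ``#`` starts a comment; node order is file order.
    """
    pairs = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if re.sub(r"\s+", "", line).lower() != "targets,factors":
                raise ParseError("expected header 'targets, factors'", lineno)
            header_seen = True
            continue
        if "," not in line:
            raise ParseError("expected 'NAME, EXPRESSION'", lineno)
        name, expr_text = line.split(",", 1)
        name = name.strip()
        if not _NAME_RE.match(name):
            raise ParseError(f"invalid target name {name!r}", lineno)
        pairs.append((name, parse_expression(expr_text, lineno)))
    if not header_seen:
        raise ParseError("empty document: missing 'targets, factors' header", 1)
    if not pairs:
        raise ParseError("no rules found after header", 1)
    return BooleanNetwork.from_rules(pairs, input_names, strict=strict)


def write_network(net: BooleanNetwork) -> str:
    """Serialize a network back to BoolNet-dialect text (node order preserved)."""
    lines = ["targets, factors"]
    for name in net.nodes:
        lines.append(f"{name}, {to_string(net.rules[name])}")
    return "\n".join(lines) + "\n"
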