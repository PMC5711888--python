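"""In-silico mutations, noise-robustness experiments and rule sensitivity.

A gain- (clamp to 1) or loss-of-function (clamp to 0) mutation replaces a
node's update rule with a constant for the whole analysis.  Robustness to
molecular activation noise is probed with Hamming-distance-1 perturbations
of uniformly random initial states: the original and the perturbed copy
are iterated to their attractors and compared, either by canonical
attractor identity or by the behavior label the attractor carries.  Rule
sensitivity is the one-step analogue: the probability that a single
random flip changes a rule's output, which equals the mean Boolean
influence of its inputs over the network size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from ._vectorized import flip_random_bit, random_states, trajectory_attractors
from .angiomodel import (
    ATYPICAL,
    LABELS,
    PHALANX,
    STALK,
    TIP,
    SweepSummary,
    sweep_environments,
)
from .netcore import And, BooleanNetwork, Const, Expr, NetworkError, Not, Or, Var

__all__ = [
    "MutationSpec",
    "apply_mutation",
    "all_single_mutations",
    "mutation_scan",
    "MutationScanReport",
    "perturb_state",
    "robustness_experiment",
    "RobustnessResult",
    "rule_sensitivity",
    "SensitivityResult",
]


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """A single gain- or loss-of-function mutation."""

    node: str
    kind: str  # "loss" (clamp 0) or "gain" (clamp 1)

    def __post_init__(self):
        if self.kind not in ("loss", "gain"):
            raise NetworkError(f"mutation kind must be 'loss' or 'gain', got {self.kind!r}")

    @property
    def value(self) -> int:
        return 0 if self.kind == "loss" else 1

    def __str__(self):
        return f"{self.node}:{self.kind}"


def apply_mutation(net: BooleanNetwork, mutation: MutationSpec) -> BooleanNetwork:
    """Clamp the target's rule to the mutation constant.

    Input nodes are clamped the same way as internal nodes; a swept mutant
    then effectively explores 2^15 distinct environments, still reported
    over the full code range.
    """
    return net.replace_rule(mutation.node, Const(mutation.value))


def all_single_mutations(net: BooleanNetwork) -> list:
    """All loss and gain clamps, two per node, in node order."""
    return [
        MutationSpec(node, kind) for node in net.nodes for kind in ("loss", "gain")
    ]


@dataclass
class MutationScanReport:
    """Per-mutation environment sweeps against the wild-type reference.

    ``classification`` maps each mutation to one of ``"no_effect"``
    (identical per-environment label vector), ``"behavior_lost"`` (some
    signature appears in no attractor of any environment) or
    ``"response_changed"``.  The three classes partition the scan.
    """

    wild_type: SweepSummary
    rows: list = field(default_factory=list)  # (MutationSpec, SweepSummary)

    def classification(self) -> dict:
        out = {}
        wt = self.wild_type.env_labels
        for spec, summary in self.rows:
            if bool(np.array_equal(summary.env_labels, wt)):
                out[spec] = "no_effect"
            elif not all(summary.behavior_present.values()):
                out[spec] = "behavior_lost"
            else:
                out[spec] = "response_changed"
        return out

    def lost_behaviors(self) -> dict:
        """Mutation -> set of behaviors with no attractor anywhere."""
        return {
            spec: {b for b, present in summary.behavior_present.items() if not present}
            for spec, summary in self.rows
        }

    def aggregate(self) -> dict:
        cls = self.classification()
        lost = self.lost_behaviors()
        counts = {"no_effect": 0, "response_changed": 0, "behavior_lost": 0}
        per_behavior = {"Phalanx": 0, "Stalk": 0, "Tip": 0}
        for spec in cls:
            counts[cls[spec]] += 1
            for b in lost[spec]:
                per_behavior[b] += 1
        return {"classes": counts, "behavior_loss": per_behavior, "n": len(self.rows)}

    def to_dataframe(self):
        import pandas as pd

        cls = self.classification()
        lost = self.lost_behaviors()
        rows = []
        for spec, summary in self.rows:
            counts = summary.behavior_counts()
            rows.append(
                {
                    "node": spec.node,
                    "kind": spec.kind,
                    **{f"env_{k.lower()}": v for k, v in counts.items()},
                    "class": cls[spec],
                    "lost": ",".join(sorted(lost[spec])),
                }
            )
        return pd.DataFrame(rows)


def mutation_scan(
    net: BooleanNetwork,
    mutations: Iterable[MutationSpec] | None = None,
    backend: str = "auto",
    wild_type: SweepSummary | None = None,
    progress: bool = False,
) -> MutationScanReport:
    """Full environment sweep under each clamp (all 2n by default)."""
    if mutations is None:
        mutations = all_single_mutations(net)
    if wild_type is None:
        wild_type = sweep_environments(net, backend=backend)
    report = MutationScanReport(wild_type=wild_type)
    for spec in mutations:
        if progress:
            print(f"  scanning {spec} ...")
        summary = sweep_environments(apply_mutation(net, spec), backend=backend)
        report.rows.append((spec, summary))
    return report


# ---------------------------------------------------------------------------
# Noise robustness
# ---------------------------------------------------------------------------

def perturb_state(state: int, n_nodes: int, rng: np.random.Generator) -> int:
    """Hamming-distance-1 copy: one uniformly chosen node flipped."""
    return state ^ (1 << int(rng.integers(0, n_nodes)))


@dataclass(frozen=True)
class RobustnessResult:
    """Outcome of a Hamming-distance-1 robustness experiment.

    Fractions are the share of replicates whose perturbed copy reached the
    same attractor (``attractor`` mode) or an attractor with the same
    behavior label (``behavior`` mode).  ``per_behavior`` conditions on the
    label of the unperturbed trajectory's attractor; denominators are the
    replicate counts of those "relevant experiments".
    """

    mode: str
    n: int
    seed: int
    fraction_unchanged: float
    per_behavior: dict = field(default_factory=dict)  # label -> (fraction, denominator)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n": self.n,
            "seed": self.seed,
            "fraction_unchanged": self.fraction_unchanged,
            "per_behavior": {
                k: {"fraction": f, "n_relevant": d}
                for k, (f, d) in self.per_behavior.items()
            },
        }


def _attractor_label_codes(shared_state_labels: np.ndarray) -> np.ndarray:
    """Lift shared per-state labels to attractor-level codes: a cycle whose
    states agree on a signature keeps it, anything else is atypical."""
    lifted = shared_state_labels.copy()
    lifted[(shared_state_labels <= 0)] = ATYPICAL
    return lifted


def robustness_experiment(
    net: BooleanNetwork,
    mode: str,
    n: int,
    seed: int,
    label_fn: Callable | None = None,
) -> RobustnessResult | tuple:
    """Monte-Carlo robustness to molecular activation noise.

    Draws ``n`` uniform random full-network states, flips one uniformly
    chosen variable in a copy (inputs included — the flip may change the
    micro-environment itself), iterates both to their attractors and
    compares.  ``mode`` is ``"attractor"``, ``"behavior"`` or ``"both"``
    (returning a pair).  ``label_fn`` maps packed-state arrays to state
    label codes; the bundled model's marker labeler is used by default.
    """
    if mode not in ("attractor", "behavior", "both"):
        raise NetworkError(f"unknown robustness mode {mode!r}")
    if n < 1:
        raise NetworkError("n must be at least 1")
    if label_fn is None:
        label_fn = state_labeler(net)
    rng = np.random.default_rng(seed)
    originals = random_states(net, rng, n)
    perturbed = flip_random_bit(originals, net.n, rng)
    ids_o, lab_o = trajectory_attractors(net, originals, label_fn)
    ids_p, lab_p = trajectory_attractors(net, perturbed, label_fn)
    att_o = _attractor_label_codes(lab_o)
    att_p = _attractor_label_codes(lab_p)

    def build(which: str) -> RobustnessResult:
        same = (ids_o == ids_p) if which == "attractor" else (att_o == att_p)
        per = {}
        for code in (PHALANX, STALK, TIP):
            mask = att_o == code
            denom = int(mask.sum())
            frac = float(same[mask].mean()) if denom else float("nan")
            per[LABELS[code]] = (frac, denom)
        return RobustnessResult(
            mode=which,
            n=n,
            seed=seed,
            fraction_unchanged=float(same.mean()),
            per_behavior=per,
        )

    if mode == "both":
        return build("attractor"), build("behavior")
    return build(mode)


def state_labeler(net: BooleanNetwork) -> Callable:
    """Vectorized marker classifier for packed-state arrays.

    Returns codes 0 (none), 1 Phalanx, 2 Stalk, 3 Tip.  Networks without
    the marker nodes get the all-zero labeler (every attractor is then
    "atypical", which still compares consistently in behavior mode).
    """
    from .angiomodel import _signatures

    sigs = _signatures()["signatures"]
    needed = {m for sig in sigs.values() for m in sig}
    if not needed <= set(net.nodes):
        return lambda s: np.zeros(s.shape[0], dtype=np.int64)
    idx = {m: np.uint64(net.index(m)) for m in needed}

    def label(states: np.ndarray) -> np.ndarray:
        bit = {m: (states >> i) & np.uint64(1) for m, i in idx.items()}
        out = np.zeros(states.shape[0], dtype=np.int64)
        for code, name in ((PHALANX, "Phalanx"), (STALK, "Stalk"), (TIP, "Tip")):
            match = np.ones(states.shape[0], dtype=bool)
            for m, v in sigs[name].items():
                match &= bit[m] == v
            out[match] = code
        return out

    return label


# ---------------------------------------------------------------------------
# Rule sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityResult:
    """Per-rule one-step flip probabilities.

    ``estimates`` are Monte-Carlo, ``analytic`` the exact mean Boolean
    influence over the network size (computed from the rule's truth table
    whenever its support is small enough to enumerate).
    """

    n: int
    seed: int
    estimates: dict          # node -> estimated flip probability
    analytic: dict           # node -> exact influence sum / n_nodes (or None)

    @property
    def mean_estimate(self) -> float:
        return float(np.mean(list(self.estimates.values())))

    def max_node(self) -> str:
        return max(self.estimates, key=self.estimates.get)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": list(self.estimates),
                "estimate": list(self.estimates.values()),
                "analytic": [self.analytic[n] for n in self.estimates],
                "n": self.n,
                "seed": self.seed,
            }
        )


def _truth_table(expr: Expr, support: list) -> np.ndarray:
    """Rule outputs over all assignments of its support, vectorized."""
    k = len(support)
    idx = np.arange(1 << k, dtype=np.uint32)
    cols = {name: (idx >> i) & 1 for i, name in enumerate(support)}

    def ev(e: Expr) -> np.ndarray:
        t = type(e)
        if t is Var:
            return cols[e.name]
        if t is Const:
            return np.full(idx.shape, e.value, dtype=np.uint32)
        if t is Not:
            return 1 - ev(e.child)
        parts = [ev(c) for c in e.children]
        out = parts[0]
        if t is And:
            for p in parts[1:]:
                out = out & p
        else:
            for p in parts[1:]:
                out = out | p
        return out

    return ev(expr).astype(np.uint8)


ANALYTIC_SUPPORT_CAP = 20


def analytic_sensitivity(net: BooleanNetwork, node: str) -> float | None:
    """Exact sensitivity: sum of the Boolean influences of each variable
    (probability a flip of that variable alone changes the rule output
    under a uniform state) divided by the network size."""
    expr = net.rules[node]
    support = sorted(expr.variables())
    if len(support) > ANALYTIC_SUPPORT_CAP:
        return None
    table = _truth_table(expr, support)
    idx = np.arange(table.shape[0], dtype=np.uint32)
    infl_sum = 0.0
    for j in range(len(support)):
        flipped = table[idx ^ (1 << j)]
        infl_sum += float((table != flipped).mean())
    return infl_sum / net.n


def rule_sensitivity(net: BooleanNetwork, n: int, seed: int) -> SensitivityResult:
    """Monte-Carlo sensitivity of every update-rule component.

    For each rule: ``n`` uniform random states, one uniformly chosen
    network variable flipped per state, rule applied once to both; the
    estimate is the fraction of differing outputs.  The analytic value
    anchors the estimate (they agree within binomial sampling error).
    """
    if n < 1:
        raise NetworkError("n must be at least 1")
    rng = np.random.default_rng(seed)
    estimates = {}
    analytic = {}
    for node in net.nodes:
        expr = net.rules[node]
        support = sorted(expr.variables())
        k = len(support)
        if k == 0:
            estimates[node] = 0.0
            analytic[node] = 0.0
            continue
        table = _truth_table(expr, support)
        states = rng.integers(0, 1 << k, size=n, dtype=np.uint32)
        flip_var = rng.integers(0, net.n, size=n)
        # flips of variables outside the support never change the output
        pos = {net.index(name): j for j, name in enumerate(support)}
        flip_pos = np.full(n, -1, dtype=np.int32)
        for global_idx, j in pos.items():
            flip_pos[flip_var == global_idx] = j
        in_support = flip_pos >= 0
        flipped_states = states.copy()
        flipped_states[in_support] ^= (
            np.uint32(1) << flip_pos[in_support].astype(np.uint32)
        )
        differs = table[states] != table[flipped_states]
        estimates[node] = float(differs.mean())
        analytic[node] = analytic_sensitivity(net, node)
    return SensitivityResult(n=n, seed=seed, estimates=estimates, analytic=analytic)
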