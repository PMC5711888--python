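"""The bundled 64-node angiogenesis model and its behavior analysis.

The model describes one endothelial cell (EC) as a synchronous Boolean
network: 48 internal signaling nodes driven by 16 micro-environment inputs
(growth-factor ligands, oxygen, the AMP:ATP energy ratio, shear stress).
Attractors are read as cell behaviors through marker signatures:

* Tip      — NRP1 active, autocrine DLL4 active, AKT inactive;
* Stalk    — autocrine JAG1 active, NRP1 inactive;
* Phalanx  — AKT active, autocrine JAG1 and NRP1 inactive.

A micro-environment *causes* a behavior when every one of its attractors
carries the same signature in every state; environments with mixed or
unrecognized patterns are atypical.  An attractor is proliferative when
betacatenin and LEF1 are active throughout (cyclin D1-mediated cell-cycle
entry requires both).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Mapping

import numpy as np

from .attractors import (
    Attractor,
    MicroEnvironment,
    core_orbits,
    iterate_to_attractor,
    propagate_constants,
)
from .netcore import BooleanNetwork, Const, NetworkError, parse_network, to_string

__all__ = [
    "LABELS",
    "load_model",
    "load_metadata",
    "classify_state",
    "classify_attractor",
    "classify_proliferation",
    "sweep_environments",
    "behavior_transition",
    "group_environments",
    "SweepSummary",
    "TransitionResult",
]

#: label codes used in sweep arrays; 0 is the state-level "no signature"
LABELS = ("Other", "Phalanx", "Stalk", "Tip", "Atypical")
OTHER, PHALANX, STALK, TIP, ATYPICAL = range(5)

_MODEL_DIR = files("angionet") / "models"


def load_metadata() -> dict:
    """Input order, marker signatures, proliferation markers, name aliases."""
    return json.loads((_MODEL_DIR / "angiogenesis64.json").read_text())


def load_model() -> tuple:
    """The bundled 64-node network and its metadata, ``(net, meta)``."""
    meta = load_metadata()
    net = parse_network((_MODEL_DIR / "angiogenesis64.bnet").read_text(), meta["inputs"])
    return net, meta


_SIGNATURES = None


def _signatures() -> dict:
    global _SIGNATURES
    if _SIGNATURES is None:
        meta = load_metadata()
        _SIGNATURES = {
            "signatures": {k: dict(v) for k, v in meta["signatures"].items()},
            "proliferation": dict(meta["proliferation"]),
        }
    return _SIGNATURES


def classify_state(assignment: Mapping[str, int]) -> str:
    """State-level behavior label from the marker signature, else ``Other``.

    ``assignment`` must cover NRP1, DLL4a, AKT and JAGa; the three
    signatures are pairwise unsatisfiable so at most one can match.
    """
    for label, sig in _signatures()["signatures"].items():
        try:
            if all(assignment[m] == v for m, v in sig.items()):
                return label
        except KeyError as exc:
            raise NetworkError(f"state does not assign marker node {exc}") from None
    return "Other"


def classify_attractor(net: BooleanNetwork, attractor: Attractor) -> str:
    """Attractor-level label: the shared state label, else ``Atypical``.

    A cycle alternating between behaviors, or containing any state that
    matches no signature, is atypical.
    """
    labels = {classify_state(net.unpack_state(s)) for s in attractor.states}
    if len(labels) == 1:
        label = labels.pop()
        if label != "Other":
            return label
    return "Atypical"


def classify_proliferation(net: BooleanNetwork, attractor: Attractor) -> bool:
    """True when the attractor divides: betacatenin and LEF1 active in
    every state (a sustained growth signal)."""
    prolif = _signatures()["proliferation"]
    return all(
        all(net.unpack_state(s)[m] == v for m, v in prolif.items())
        for s in attractor.states
    )


# ---------------------------------------------------------------------------
# The 2^16 micro-environment sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepSummary:
    """Per-environment classification of the full 2^16 input space.

    Arrays are indexed by environment code (first declared input = most
    significant bit).  ``behavior_present`` records which attractor-level
    labels occur anywhere in the sweep — the existence flags used by the
    mutation scan.
    """

    inputs: tuple
    env_labels: np.ndarray          # label code per env (PHALANX..ATYPICAL)
    n_attractors: np.ndarray        # exact attractor count per env
    n_dividing: np.ndarray          # attractors with sustained betacatenin & LEF1
    behavior_present: dict = field(default_factory=dict)
    backend: str = "auto"

    @property
    def n_environments(self) -> int:
        return int(self.env_labels.shape[0])

    def behavior_counts(self) -> dict:
        return {
            LABELS[code]: int((self.env_labels == code).sum())
            for code in (PHALANX, STALK, TIP, ATYPICAL)
        }

    def proliferation_counts(self) -> dict:
        all_divide = self.n_dividing == self.n_attractors
        none_divide = self.n_dividing == 0
        return {
            "all": int(all_divide.sum()),
            "some": int((~all_divide & ~none_divide).sum()),
            "none": int(none_divide.sum()),
        }

    def input_active(self, name: str) -> np.ndarray:
        """Boolean mask over env codes where the named input is active."""
        pos = len(self.inputs) - 1 - self.inputs.index(name)
        codes = np.arange(self.n_environments, dtype=np.uint32)
        return ((codes >> pos) & 1).astype(bool)

    def label_mask(self, label: str) -> np.ndarray:
        return self.env_labels == LABELS.index(label)

    def to_dataframe(self):
        import pandas as pd

        codes = np.arange(self.n_environments, dtype=np.uint32)
        data = {"env_code": codes}
        for name in self.inputs:
            data[name] = self.input_active(name).astype(np.uint8)
        data["n_attractors"] = self.n_attractors
        data["behavior"] = [LABELS[c] for c in self.env_labels]
        all_div = self.n_dividing == self.n_attractors
        none_div = self.n_dividing == 0
        data["proliferation"] = np.where(all_div, "all", np.where(none_div, "none", "some"))
        return pd.DataFrame(data)


def _orbit_labels(orbit: list, fixed: Mapping[str, int], sigs: dict) -> tuple:
    """(attractor label code, divides) for one core orbit given the
    propagated constants."""
    prolif = sigs["proliferation"]
    state_labels = set()
    divides = True
    for state in orbit:
        merged_get = state.get
        values = {}
        for m in _MARKERS:
            v = merged_get(m)
            values[m] = fixed[m] if v is None else v
        for code, (label, sig) in enumerate(
            (("Phalanx", sigs["signatures"]["Phalanx"]),
             ("Stalk", sigs["signatures"]["Stalk"]),
             ("Tip", sigs["signatures"]["Tip"])),
            start=1,
        ):
            if all(values[m] == v for m, v in sig.items()):
                state_labels.add(code)
                break
        else:
            state_labels.add(OTHER)
        if divides and any(values[m] != v for m, v in prolif.items()):
            divides = False
    if len(state_labels) == 1:
        code = state_labels.pop()
        if code != OTHER:
            return code, divides
    return ATYPICAL, divides


_MARKERS = ("NRP1", "DLL4a", "AKT", "JAGa", "betacatenin", "LEF1")


def sweep_environments(
    net: BooleanNetwork,
    backend: str = "auto",
    progress: bool = False,
) -> SweepSummary:
    """Exact attractor enumeration and behavior classification for every
    assignment of the declared inputs.

    Environments whose clamped networks fold to the same free core share
    one enumeration (the model collapses to a few hundred distinct cores),
    which is what makes the full sweep affordable.  Mutant networks whose
    clamped node is an input are swept over all 2^k codes with the clamp
    overriding the corresponding input bit, so mutant summaries stay
    comparable position-by-position with the wild type.
    """
    inputs = tuple(net.inputs)
    k = len(inputs)
    n_env = 1 << k
    sigs = _signatures()
    # a gain/loss clamp on an input overrides whatever the code says
    const_inputs = {
        n: net.rules[n].value for n in inputs if type(net.rules[n]) is Const
    }
    env_labels = np.empty(n_env, dtype=np.uint8)
    n_attractors = np.empty(n_env, dtype=np.int32)
    n_dividing = np.empty(n_env, dtype=np.int32)
    present: set = set()
    cache: dict = {}
    for code in range(n_env):
        assignment = {
            name: (code >> (k - 1 - i)) & 1 for i, name in enumerate(inputs)
        }
        assignment.update(const_inputs)
        fixed, free_rules = propagate_constants(net, assignment)
        names = [n for n in net.nodes if n in free_rules]
        key = (
            tuple(fixed.get(m) for m in _MARKERS),
            tuple((n, to_string(free_rules[n])) for n in names),
        )
        res = cache.get(key)
        if res is None:
            orbits = core_orbits(names, free_rules, backend)
            att_codes = []
            divides = 0
            for orbit in orbits:
                label_code, div = _orbit_labels(orbit, fixed, sigs)
                att_codes.append(label_code)
                divides += div
            label_set = set(att_codes)
            if len(label_set) == 1 and (only := label_set.pop()) != ATYPICAL:
                env_label = only
            else:
                env_label = ATYPICAL
            res = (env_label, len(orbits), divides, frozenset(att_codes))
            cache[key] = res
        env_labels[code] = res[0]
        n_attractors[code] = res[1]
        n_dividing[code] = res[2]
        present.update(res[3])
        if progress and code % 8192 == 8191:
            print(f"  swept {code + 1}/{n_env} environments ({len(cache)} cores)")
    return SweepSummary(
        inputs=inputs,
        env_labels=env_labels,
        n_attractors=n_attractors,
        n_dividing=n_dividing,
        behavior_present={LABELS[c]: (c in present) for c in (PHALANX, STALK, TIP)},
        backend=backend,
    )


# ---------------------------------------------------------------------------
# Behavior transitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionResult:
    trajectory: tuple           # packed states from the re-environed start
    attractor: Attractor
    label: str
    transient_length: int


def behavior_transition(
    net: BooleanNetwork,
    start: int,
    new_env: MicroEnvironment,
    require_attractor: bool = True,
) -> TransitionResult:
    """Move a converged cell into a new micro-environment and re-converge.

    Only the input bits are overwritten — the internal state of the cell is
    carried over unchanged — then the trajectory is iterated to its new
    attractor.  ``start`` must lie inside an attractor unless
    ``require_attractor=False``.
    """
    if require_attractor:
        _, transient = iterate_to_attractor(net, start)
        if transient != 0:
            raise NetworkError(
                "transition start state is not part of an attractor "
                "(pass require_attractor=False to allow)"
            )
    s = start
    for name, value in new_env.assignment.items():
        bit = 1 << net.index(name)
        s = (s | bit) if value else (s & ~bit)
    attractor, transient = iterate_to_attractor(net, s)
    step = net.step_function()
    trajectory = [s]
    for _ in range(transient + attractor.length - 1):
        trajectory.append(step(trajectory[-1]))
    return TransitionResult(
        trajectory=tuple(trajectory),
        attractor=attractor,
        label=classify_attractor(net, attractor),
        transient_length=transient,
    )


# ---------------------------------------------------------------------------
# Grouping report (shared input characteristics)
# ---------------------------------------------------------------------------

def group_environments(summary: SweepSummary, label: str) -> list:
    """Disjoint groups of same-label environments described by shared
    input literals (recursive subcube cover; deterministic).

    Group numbering is a presentation artifact — only the per-label totals
    are meaningful.
    """
    codes = np.nonzero(summary.label_mask(label))[0]
    k = len(summary.inputs)
    groups: list = []

    def describe(sub: np.ndarray, free_positions: list, shared: dict):
        if sub.size == 0:
            return
        for i in list(free_positions):
            bits = (sub >> (k - 1 - i)) & 1
            if bits.min() == bits.max():
                shared = {**shared, summary.inputs[i]: int(bits[0])}
                free_positions = [j for j in free_positions if j != i]
        if sub.size == 1 << len(free_positions):  # an exact subcube
            groups.append({"shared": shared, "n_environments": int(sub.size)})
            return
        split = free_positions[0]
        bits = (sub >> (k - 1 - split)) & 1
        describe(sub[bits == 0], free_positions, shared)
        describe(sub[bits == 1], free_positions, shared)

    describe(codes.astype(np.int64), list(range(k)), {})
    return groups
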