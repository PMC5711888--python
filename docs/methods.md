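# Methods

## The model

`angionet` ships a synchronous Boolean network of endothelial-cell (EC)
behavior control during sprouting angiogenesis: 64 nodes, of which 16 are
extracellular micro-environment inputs (`VEGFC_Dp`, `VEGFAxxxP`, `ANG1`,
`Oxygen`, `ShearStress`, `JAGp`, `DLL4p`, `WNT5a`, `WNT7a`, `FGF`, `IGF`,
`BMP9`, `BMP10`, `TGFB1`, `VEGFC_D`, `AMPATP`) and 48 are intracellular
species spanning the ANG/TIE, HIF, AMPK/mTOR, VEGF, IGF, FGF,
PLCγ/calcium, PI3K/AKT, NO, NOTCH, WNT and TGF-β pathways plus the
mechanosensory machinery. Every variable is binary (sufficient activity
or not), and all variables update simultaneously:

    x(t+1) = f(x(t)),   f_i a Boolean expression over x(t).

Inputs carry identity self-loops, so a micro-environment — one of the
2^16 assignments of the 16 inputs — is constant along any trajectory.
Attractors (fixed points and cycles of `f`) are the model's stable
molecular-activation patterns. The suffixes in the VEGF node names
distinguish paracrine (`...P`), autocrine (`...A`), proteolytically
processed (`_Dp`) and anti-angiogenic (`...d`) ligand pools. `betacatenin`
is the ASCII spelling of β-catenin (the metadata file carries the display
alias).

One printed parenthesization ambiguity in the source rules (the VEGFR2
homodimer rule) is resolved in the bundled file as
`Vegfr2 & (PECAM1 | ((VEGFC_Dp | VEGFAxxx) & !(VEGFAxxxd | HIF1)))`, the
only closing consistent with the opened groups.

Behavior is read from marker signatures: **Tip** = NRP1 ∧ DLL4a ∧ ¬AKT,
**Stalk** = JAGa ∧ ¬NRP1, **Phalanx** = AKT ∧ ¬JAGa ∧ ¬NRP1 (pairwise
unsatisfiable). An attractor carries a behavior label only if *every*
state of its cycle matches that one signature; anything mixed or
unrecognized is *atypical*. A micro-environment causes a behavior when
all its attractors carry the same label; otherwise it is atypical. An
attractor is proliferative when β-catenin and LEF1 are active in every
state (cyclin D1-mediated cell-cycle entry needs both sustained); an
environment is rolled up as all / some / none of its attractors dividing.

## Exact attractor enumeration

`enumerate_attractors_env` clamps the inputs and returns the complete
attractor set of the clamped network. Exactness is the design constraint;
speed comes from structure, never sampling:

1. **Constant propagation.** Clamped inputs are substituted and rules
   folded (constant folding only) to a fixpoint. This is sound for
   attractors: a rule that folds to a constant forces its node after one
   step, so every recurrent state satisfies the propagated constants.
   Across the bundled model the 65,536 clamped networks collapse to ~400
   distinct free cores of 0–39 nodes; the sweep memoizes per core.
2. **SCC layering** (cores whose strongly connected components are all
   ≤ 13 nodes). Components are processed in condensation order; for each
   upstream periodic orbit of period p, the p-step return map over a
   component's 2^m states is built explicitly and its cycles extended.
   Each cycle of the return map corresponds to exactly one attractor of
   the extended prefix.
3. **Pointer doubling** (cores ≤ 20 nodes with a larger SCC). The full
   successor table is built with the bit-parallel step and squared k
   times; the image of f^(2^k) is exactly the recurrent set, partitioned
   into cycles by direct walking.
4. **Simulate-then-certify** (larger cores, up to 39 nodes here).
   Candidate attractors are harvested by trajectory iteration from a
   fixed battery of start states; completeness is then *proved* with a
   reduced-ordered-BDD computation: the set of states whose forward orbit
   never meets a known attractor is the greatest fixpoint of
   `X ↦ X ∧ Pre(X)`, where the preimage `Pre` of a deterministic map is
   BDD vector composition. An empty fixpoint certifies completeness; a
   nonempty one yields a counterexample state whose trajectory is a new
   attractor, and the loop repeats. The candidate battery uses a fixed
   internal seed and only shortens the counterexample loop — the result
   is seed-independent.

The BDD engine is part of the package (`angionet.bdd`): a pure-Python
reduced-ordered-BDD manager plus a numba-jitted kernel (`_bddkern`) with
an exact open-addressing unique table, lossy direct-mapped operation
caches, epoch-based O(1) resets and mark-and-rebuild garbage collection.
Variable order is the reversed depth-first post-order of the dependency
graph (each node above its regulators), which keeps signaling-cascade
diagrams compact. Without numba the pure-Python manager is used; results
are identical, only slower.

All backends are cross-checked against each other and against the 2^n
brute-force oracle on batteries of seeded random networks (the oracle
itself is the spec for "exact"): see `tests/test_acceptance.py`.

## The environment sweep and mutation scan

`sweep_environments` classifies every input assignment (exact enumeration
per environment, memoized per folded core; 2–3 minutes on one core for
the wild type). A mutation is a clamp — the target's rule replaced by a
constant for the whole analysis (`loss` = 0, `gain` = 1; 128 single
mutations for 64 nodes). Mutants are swept identically; clamping an input
overrides the corresponding bit of every environment code, so mutant
summaries stay position-comparable with the wild type (effectively 2^15
distinct environments reported over all 2^16 codes). A mutation is
classified *no effect* (identical per-environment label vector),
*behavior lost* (some signature appears in no attractor of any
environment) or *response changed*. The full 128-clamp scan is
API-supported but long-running; the test suite exercises the seven named
clamps with published phenotypes (Tip-eliminating losses of DLL4a, ETS,
MEK, NRP1; Stalk-eliminating gains of VEGFAxxxP, VEGFC_Dp, NRP1).

## Noise robustness and rule sensitivity

`robustness_experiment(net, mode, n, seed)` draws n initial states
uniformly over all 64 bits, flips one uniformly chosen variable per copy
(inputs included — a flipped input changes the micro-environment itself,
and the experiment deliberately counts that as noise), iterates both
trajectories to their attractors with the bit-parallel engine (Brent
cycle detection, then one canonicalizing walk around each cycle), and
compares: in `attractor` mode by canonical attractor identity (equality
of cycle state-sets, phase-free), in `behavior` mode by the attractor's
behavior label. Per-behavior fractions condition on the unperturbed
trajectory's label; their denominators ("relevant experiments") are
reported alongside. Million-replicate runs take seconds.

A definitional caveat: behavior-level robustness and its per-behavior
breakdown are insensitive to how attractor identity is encoded, but
attractor-level robustness is not. With canonical state-set equality —
the definition implemented here — an input flip (25% of perturbations)
can never match, and internal flips match whenever the cell re-converges
to the same cycle at any phase; phase-locked comparison gives nearly the
same number (≈70% vs ≈71% at n = 10^5). Stricter comparators used by
other toolchains (e.g. indices into separately computed attractor lists)
can report much lower values on identical dynamics; the attractor-mode
number should therefore only be compared across tools with the
comparator pinned down.

`rule_sensitivity(net, n, seed)` estimates, for every component f_i, the
probability that one uniformly chosen variable flip changes its output on
a uniform random state, and computes the analytic value exactly from the
rule's truth table: the mean Boolean influence of its inputs divided by
the network size (64). Estimates agree with the analytic anchor within
binomial sampling error; rules are small (support ≤ 8 here), so the
analytic path is always available.

## Network reduction

Three attractor-aware operators with replayable logs: removal of
constant inputs (fold the constant everywhere; attractors of the reduced
network are the originals restricted to that input value, projected),
removal of out-degree-0 outputs (projection preserves all attractors),
and contraction of unprotected relay nodes with in- or out-degree one
(literal substitution with polarity, or rule inlining; contractions that
would create a self-loop are skipped, so feedback circuits survive).
Under synchronous update, inlining shifts the timing of cycles, so only
fixed points are guaranteed to survive contraction unchanged — the tests
assert exactly that, plus full attractor preservation for the other two
operators, on brute-forceable fixtures. The protected set (in practice,
transcription factors) is caller-supplied.

## Problem sizes and numerical choices

* The wild-type sweep and the mutant sweeps in the tests are exact and
  deterministic; no tolerance applies.
* Robustness tests run at n = 100,000 with tolerances widened to several
  binomial standard errors (overall fractions have SE ≈ 0.05–0.15
  percentage points at that scale; the Phalanx-conditioned fraction has a
  denominator of only ~0.3% of replicates and gets a proportionally wide
  band). The acceptance script runs the experiments at n = 1,000,000.
* Sensitivity runs at n = 500,000 per rule, matched by a 4-standard-error
  agreement bound against the analytic values.
* All stochastic experiments take an explicit integer seed and are
  bit-reproducible for identical (n, seed).
* Ties and canonical forms: states are packed integers (bit i = node i in
  file order); an attractor's canonical form starts at its minimum state;
  environment codes pack the declared inputs first-input-most-significant.

## What the random fixtures do and do not show

Property tests use seeded random networks (1–20 nodes, in-degrees 1–4,
unbiased truth tables) as oracle-checkable stand-ins. They exercise the
enumeration machinery across topologies far denser in feedback than the
curated model, but they are not biological: passing them demonstrates
algorithmic correctness (backend-oracle agreement, closure, minimality,
canonicalization, replayability), not biological validity of any
particular rule set.

## Known limitations

* Single-cell scope: no lateral-inhibition coupling between neighboring
  cells, no spatial gradients, no sprout geometry; multicellular readouts
  (mural-cell recruitment, lumen formation) are outside the model.
* Synchronous update only; race conditions and update-order effects are
  not represented.
* The contraction operator preserves cyclic attractors' existence on the
  tested fixtures but not their length or phase (inherent to synchronous
  inlining).
* The symbolic backend's certificate cost depends on BDD size; the
  bundled model's hardest cores need garbage collection but stay within
  ~1.5 GB. Pathological rule sets could exceed the node pool, which is a
  declared error (never a silent partial result).
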