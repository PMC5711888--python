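"""Numba-jitted kernel behind the accelerated decision-diagram manager.

Same reduced-ordered-BDD semantics as the pure-Python manager in
:mod:`angionet.bdd`, with node storage in flat arrays, an exact
open-addressing unique table (canonicity) and lossy direct-mapped caches
for the ``ite`` and ``compose`` operators (collisions overwrite — results
are recomputed, never wrong).  All tables are epoch-tagged so that a fresh
manager on the shared arrays costs nothing to set up; the kernel is what
makes certified attractor enumeration on the hardest clamped cores a
sub-second affair.

Node ids: 0 and 1 are the terminals; levels are int8 (< 127 variables).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: node capacity per manager epoch (overflow raises into the fallback)
NODE_CAP = 1 << 25
_UNIQ_SIZE = 1 << 26          # open-addressing slots (power of two)
_MEMO_SIZE = 1 << 22          # direct-mapped ite cache
_CMEMO_SIZE = 1 << 21         # direct-mapped compose cache

TERMINAL_LEVEL = 127


def new_state():
    """Allocate the kernel arrays (shared by all managers in a process)."""
    lvl = np.empty(NODE_CAP, dtype=np.int8)
    lo = np.empty(NODE_CAP, dtype=np.int32)
    hi = np.empty(NODE_CAP, dtype=np.int32)
    lvl[0] = lvl[1] = TERMINAL_LEVEL
    lo[0] = hi[0] = 0
    lo[1] = hi[1] = 1
    uniq = np.full(_UNIQ_SIZE, -1, dtype=np.int32)
    uniq_ep = np.zeros(_UNIQ_SIZE, dtype=np.int32)
    memo_key = np.full(_MEMO_SIZE, -1, dtype=np.int64)   # f | g<<25 | ep<<50
    memo_h = np.empty(_MEMO_SIZE, dtype=np.int32)
    memo_r = np.empty(_MEMO_SIZE, dtype=np.int32)
    cmemo_key = np.full(_CMEMO_SIZE, -1, dtype=np.int64)  # node | ep<<34
    cmemo_r = np.empty(_CMEMO_SIZE, dtype=np.int32)
    used = np.array([2, 0], dtype=np.int64)  # [next node id, current epoch]
    ite_fr = np.empty((9, _STACK), dtype=np.int64)   # ite frame stack
    ite_ph = np.empty(_STACK, dtype=np.int8)
    co_fr = np.empty((3, _STACK), dtype=np.int64)    # compose frame stack
    co_ph = np.empty(_STACK, dtype=np.int8)
    return (
        lvl, lo, hi, uniq, uniq_ep, memo_key, memo_h, memo_r,
        cmemo_key, cmemo_r, used, ite_fr, ite_ph, co_fr, co_ph,
    )


@njit(cache=True, inline="always")
def _hash3(a, b, c, mask):
    x = a * np.int64(0x9E3779B1) + b * np.int64(0x85EBCA77) + c * np.int64(0xC2B2AE3D)
    x ^= x >> 15
    return x & mask


@njit(cache=True)
def _mk(level, lo_id, hi_id, lvl, lo, hi, uniq, uniq_ep, used):
    if lo_id == hi_id:
        return lo_id
    mask = np.int64(uniq.shape[0] - 1)
    epoch = used[1]
    slot = _hash3(np.int64(level), np.int64(lo_id), np.int64(hi_id), mask)
    while True:
        node = uniq[slot]
        if node < 0 or uniq_ep[slot] != epoch:
            break
        if lvl[node] == level and lo[node] == lo_id and hi[node] == hi_id:
            return np.int64(node)
        slot = (slot + 1) & mask
    node = used[0]
    if node >= lvl.shape[0]:
        raise MemoryError("bdd node capacity exceeded")
    used[0] = node + 1
    lvl[node] = level
    lo[node] = lo_id
    hi[node] = hi_id
    uniq[slot] = node
    uniq_ep[slot] = epoch
    return np.int64(node)


_STACK = 132  # ite/compose recursion depth is bounded by the level count


@njit(cache=True)
def _ite(f_in, g_in, h_in, lvl, lo, hi, uniq, uniq_ep, mk_, mh_, mr_, used, fr, ph):
    """Iterative if-then-else with an explicit frame stack.

    Frames descend one level per push, so the stack depth is bounded by
    the variable count; phase 1 = low child pending, 2 = high child
    pending.  The direct-mapped cache is epoch-keyed; the frame stack is
    caller-provided scratch (not reentrant, by design).
    """
    mask = np.int64(mk_.shape[0] - 1)
    epoch = used[1]
    fs = fr[0]
    gs = fr[1]
    hs = fr[2]
    f1s = fr[3]
    g1s = fr[4]
    h1s = fr[5]
    lvs = fr[6]
    sls = fr[7]
    r0s = fr[8]
    sp = 0
    fs[0], gs[0], hs[0], ph[0] = f_in, g_in, h_in, 0
    ret = np.int64(-1)
    have = False
    while sp >= 0:
        if have:
            if ph[sp] == 1:
                r0s[sp] = ret
                ph[sp] = 2
                sp += 1
                fs[sp], gs[sp], hs[sp], ph[sp] = f1s[sp - 1], g1s[sp - 1], h1s[sp - 1], 0
                have = False
            else:  # high child done: combine, memoize, return upward
                r = _mk(lvs[sp], r0s[sp], ret, lvl, lo, hi, uniq, uniq_ep, used)
                slot = sls[sp]
                mk_[slot] = fs[sp] | (gs[sp] << np.int64(25)) | (epoch << np.int64(50))
                mh_[slot] = hs[sp]
                mr_[slot] = r
                ret = r
                sp -= 1
            continue
        f, g, h = fs[sp], gs[sp], hs[sp]
        if f == 1 or g == h:
            ret = g
            have = True
            sp -= 1
            continue
        if f == 0:
            ret = h
            have = True
            sp -= 1
            continue
        if g == 1 and h == 0:
            ret = f
            have = True
            sp -= 1
            continue
        key = f | (g << np.int64(25)) | (epoch << np.int64(50))
        slot = _hash3(key, h, np.int64(1), mask)
        if mk_[slot] == key and mh_[slot] == h:
            ret = np.int64(mr_[slot])
            have = True
            sp -= 1
            continue
        level = lvl[f]
        if lvl[g] < level:
            level = lvl[g]
        if lvl[h] < level:
            level = lvl[h]
        if lvl[f] == level:
            f0, f1 = np.int64(lo[f]), np.int64(hi[f])
        else:
            f0, f1 = f, f
        if lvl[g] == level:
            g0, g1 = np.int64(lo[g]), np.int64(hi[g])
        else:
            g0, g1 = g, g
        if lvl[h] == level:
            h0, h1 = np.int64(lo[h]), np.int64(hi[h])
        else:
            h0, h1 = h, h
        lvs[sp] = level
        sls[sp] = slot
        f1s[sp], g1s[sp], h1s[sp] = f1, g1, h1
        ph[sp] = 1
        sp += 1
        fs[sp], gs[sp], hs[sp], ph[sp] = f0, g0, h0, 0
    return ret


@njit(cache=True)
def _compose(node_in, funcs, lvl, lo, hi, uniq, uniq_ep, mk_, mh_, mr_, ck, cr, used, ite_fr, ite_ph, fr, ph):
    """Shannon expansion of ``node_in`` with ``funcs[level]`` substituted
    for each variable: the preimage operator for a deterministic map.
    Iterative, with the per-node result cached for the current epoch."""
    mask = np.int64(ck.shape[0] - 1)
    epoch = used[1]
    ns = fr[0]
    sls = fr[1]
    c0s = fr[2]
    sp = 0
    ns[0], ph[0] = node_in, 0
    ret = np.int64(-1)
    have = False
    while sp >= 0:
        if have:
            if ph[sp] == 1:
                c0s[sp] = ret
                ph[sp] = 2
                sp += 1
                ns[sp], ph[sp] = np.int64(hi[ns[sp - 1]]), 0
                have = False
            else:
                r = _ite(
                    np.int64(funcs[lvl[ns[sp]]]), ret, c0s[sp],
                    lvl, lo, hi, uniq, uniq_ep, mk_, mh_, mr_, used, ite_fr, ite_ph,
                )
                ck[sls[sp]] = ns[sp] | (epoch << np.int64(34))
                cr[sls[sp]] = r
                ret = r
                sp -= 1
            continue
        node = ns[sp]
        if node <= 1:
            ret = node
            have = True
            sp -= 1
            continue
        key = node | (epoch << np.int64(34))
        slot = _hash3(key, np.int64(0), np.int64(1), mask)
        if ck[slot] == key:
            ret = np.int64(cr[slot])
            have = True
            sp -= 1
            continue
        sls[sp] = slot
        ph[sp] = 1
        sp += 1
        ns[sp], ph[sp] = np.int64(lo[node]), 0
    return ret


def next_epoch(state) -> None:
    """Invalidate every node and cache entry in O(1)."""
    used = state[10]
    used[0] = 2
    used[1] += 1
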