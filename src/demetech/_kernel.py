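"""Numba-accelerated within-generation engine.

Mirrors the pure-Python period loop in :mod:`demetech.dynamics` exactly in
semantics (coalition sampling scheme, better-response enumeration order,
tie-breaking, mistake model, per-period fitness accrual, inclusive 90%
adoption rule) but operates on flat arrays with numba's internal random
stream, seeded once per deme-generation.  The Python path remains the
reference implementation; tests validate this kernel against the exact
stationary distribution of an enumerated Markov chain and against the
Python path's statistics.

The graph is passed in CSR form (``indptr``, ``indices``).  One call runs up
to ``periods`` periods of ``events_per_period`` coalition updates each and
returns early when the adoption threshold is reached, so the caller can
increment the technology level, reset strategies and re-enter with a new
``alpha``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _payoff(s, old, deg, alpha):
    if s == 0:
        return old / deg
    return alpha * (deg - old) / deg


@njit(cache=True)
def _one_event(
    indptr, indices, strategies, types, old_nbrs, cur_payoff,
    alpha, k, eps, pair_prob, members, final,
):
    """Sample one coalition, compute its better response with mistakes, and
    stage the result: returns the coalition size with intended+mistake
    strategies in ``final``.  Mirrors the reference operations."""
    n = strategies.size
    u = np.random.randint(0, n)
    msize = 1
    members[0] = u
    if k >= 2 and types[u] == 1:
        # count SI neighbors of u
        c = 0
        for p in range(indptr[u], indptr[u + 1]):
            if types[indices[p]] == 1:
                c += 1
        if c > 0 and np.random.random() < pair_prob:
            if k == 2:
                target = 2
            else:
                target = 2 + np.random.randint(0, k - 1)
            # add a uniformly chosen SI neighbor of u
            pick = np.random.randint(0, c)
            for p in range(indptr[u], indptr[u + 1]):
                w = indices[p]
                if types[w] == 1:
                    if pick == 0:
                        members[msize] = w
                        msize += 1
                        break
                    pick -= 1
            # grow toward target by absorbing SI neighbors of the set
            while msize < target:
                # gather unique SI neighbors of members, excluding members
                cand = np.empty(256, np.int64)
                cc = 0
                for mi in range(msize):
                    mm = members[mi]
                    for p in range(indptr[mm], indptr[mm + 1]):
                        w = indices[p]
                        if types[w] != 1:
                            continue
                        dup = False
                        for mj in range(msize):
                            if members[mj] == w:
                                dup = True
                                break
                        if not dup:
                            for cj in range(cc):
                                if cand[cj] == w:
                                    dup = True
                                    break
                        if not dup:
                            cand[cc] = w
                            cc += 1
                if cc == 0:
                    break
                # match the reference path: candidates in sorted order
                cand[:cc].sort()
                w = cand[np.random.randint(0, cc)]
                members[msize] = w
                msize += 1
    # sort members (reference path returns sorted tuples)
    if msize == 2:
        if members[0] > members[1]:
            members[0], members[1] = members[1], members[0]
    elif msize > 2:
        for a in range(1, msize):
            key = members[a]
            b = a - 1
            while b >= 0 and members[b] > key:
                members[b + 1] = members[b]
                b -= 1
            members[b + 1] = key

    if msize == 1:
        i = members[0]
        deg = indptr[i + 1] - indptr[i]
        old = old_nbrs[i]
        p_old = old / deg
        p_new = alpha * (deg - old) / deg
        s_i = strategies[i]
        if s_i == 0:
            final[0] = 1 if p_new > p_old else 0
        else:
            final[0] = 0 if p_old > p_new else 1
    elif msize == 2:
        i = members[0]
        j = members[1]
        deg_i = indptr[i + 1] - indptr[i]
        deg_j = indptr[j + 1] - indptr[j]
        s_i = strategies[i]
        s_j = strategies[j]
        eo_i = old_nbrs[i] - (1 - s_j)
        eo_j = old_nbrs[j] - (1 - s_i)
        en_i = deg_i - 1 - eo_i
        en_j = deg_j - 1 - eo_j
        cur_i = cur_payoff[i]
        cur_j = cur_payoff[j]
        n_strict = 0
        s0 = 0
        s1 = 0
        s2 = 0
        # four assignments in lexicographic order: (0,0),(0,1),(1,0),(1,1)
        for code in range(4):
            a_i = code >> 1
            a_j = code & 1
            if a_i == 0:
                p_i = (eo_i + (1 - a_j)) / deg_i
            else:
                p_i = alpha * (en_i + a_j) / deg_i
            if p_i < cur_i:
                continue
            if a_j == 0:
                p_j = (eo_j + (1 - a_i)) / deg_j
            else:
                p_j = alpha * (en_j + a_i) / deg_j
            if p_j < cur_j:
                continue
            if p_i > cur_i or p_j > cur_j:
                if n_strict == 0:
                    s0 = code
                elif n_strict == 1:
                    s1 = code
                else:
                    s2 = code
                n_strict += 1
        if n_strict == 0:
            chosen = (s_i << 1) | s_j
        elif n_strict == 1:
            chosen = s0
        else:
            pick = np.random.randint(0, n_strict)
            chosen = s0 if pick == 0 else (s1 if pick == 1 else s2)
        final[0] = chosen >> 1
        final[1] = chosen & 1
    else:
        # general enumeration over 2^msize assignments (msize <= 4)
        ext_old = np.empty(4, np.int64)
        int_mask = np.empty(4, np.int64)  # bitmask of internal adjacency
        degs = np.empty(4, np.int64)
        cur = np.empty(4, np.float64)
        for a in range(msize):
            i = members[a]
            degs[a] = indptr[i + 1] - indptr[i]
            cur[a] = cur_payoff[i]
            eo = 0
            mask = 0
            for p in range(indptr[i], indptr[i + 1]):
                w = indices[p]
                internal = False
                for b in range(msize):
                    if members[b] == w:
                        mask |= 1 << b
                        internal = True
                        break
                if not internal and strategies[w] == 0:
                    eo += 1
            ext_old[a] = eo
            int_mask[a] = mask
        cur_assign = 0
        for a in range(msize):
            if strategies[members[a]] == 1:
                cur_assign |= 1 << a
        n_assign = 1 << msize
        strict = np.empty(16, np.int64)
        n_strict = 0
        for assign in range(n_assign):
            feasible = True
            any_strict = False
            for a in range(msize):
                mask = int_mask[a]
                # count internal neighbors of a playing OLD under assign
                internal_old = 0
                internal_all = 0
                for b in range(msize):
                    if mask & (1 << b):
                        internal_all += 1
                        if not assign & (1 << b):
                            internal_old += 1
                if assign & (1 << a):
                    ext_new = degs[a] - internal_all - ext_old[a]
                    internal_new = internal_all - internal_old
                    pay = alpha * (ext_new + internal_new) / degs[a]
                else:
                    pay = (ext_old[a] + internal_old) / degs[a]
                if pay < cur[a]:
                    feasible = False
                    break
                if pay > cur[a]:
                    any_strict = True
            if feasible and any_strict:
                strict[n_strict] = assign
                n_strict += 1
        if n_strict == 0:
            chosen = cur_assign
        elif n_strict == 1:
            chosen = strict[0]
        else:
            chosen = strict[np.random.randint(0, n_strict)]
        for a in range(msize):
            final[a] = 1 if chosen & (1 << a) else 0

    if eps > 0.0:
        for a in range(msize):
            if np.random.random() < eps:
                final[a] = 0 if np.random.random() < 0.5 else 1
    return msize


@njit(cache=True)
def _apply_final(
    indptr, indices, strategies, old_nbrs, cur_payoff, members, final,
    msize, alpha, new_count,
):
    """Commit staged strategies, patching the payoff cache; returns new_count."""
    for a in range(msize):
        i = members[a]
        s = final[a]
        if s == strategies[i]:
            continue
        strategies[i] = s
        if s == 1:
            new_count += 1
            delta = -1
        else:
            new_count -= 1
            delta = 1
        for q in range(indptr[i], indptr[i + 1]):
            w = indices[q]
            old_nbrs[w] += delta
            degw = indptr[w + 1] - indptr[w]
            cur_payoff[w] = _payoff(strategies[w], old_nbrs[w], degw, alpha)
        degi = indptr[i + 1] - indptr[i]
        cur_payoff[i] = _payoff(s, old_nbrs[i], degi, alpha)
    return new_count


@njit(cache=True)
def run_events_occupancy(
    indptr, indices, strategies, types, old_nbrs, cur_payoff,
    alpha, k, eps, pair_prob, n_events,
):
    """Run raw update events on a tiny deme, counting strategy-state visits.

    Returns occupancy counts over the 2^n strategy configurations (node i's
    strategy is bit i), sampled after every event.  Used to compare the
    kernel's long-run behavior against an exactly enumerated Markov chain.
    """
    n = strategies.size
    members = np.empty(8, np.int64)
    final = np.empty(8, np.int64)
    counts = np.zeros(1 << n, np.int64)
    new_count = 0
    for i in range(n):
        new_count += strategies[i]
    for _ in range(n_events):
        msize = _one_event(
            indptr, indices, strategies, types, old_nbrs, cur_payoff,
            alpha, k, eps, pair_prob, members, final,
        )
        new_count = _apply_final(
            indptr, indices, strategies, old_nbrs, cur_payoff,
            members, final, msize, alpha, new_count,
        )
        state = 0
        for i in range(n):
            if strategies[i] == 1:
                state |= 1 << i
        counts[state] += 1
    return counts


@njit(cache=True)
def run_segment(
    indptr, indices, strategies, types, old_nbrs, cur_payoff, cum,
    new_count, alpha, periods, events_per_period, k, eps, pair_prob,
    check_adoption,
):
    """Run up to ``periods`` periods; return (periods_done, new_count, adopted).

    Stops right after the period whose end satisfies the adoption rule (that
    period's payoffs are already accrued; the caller resets strategies and
    advances the technology level).  Fitness accrual is lazily batched over
    change-free periods.
    """
    n = strategies.size
    members = np.empty(8, np.int64)
    final = np.empty(8, np.int64)
    pending = 0  # completed periods not yet accrued (payoffs unchanged since)
    adopt_num = 9 * n
    for p in range(periods):
        for _e in range(events_per_period):
            msize = _one_event(
                indptr, indices, strategies, types, old_nbrs, cur_payoff,
                alpha, k, eps, pair_prob, members, final,
            )
            changed = False
            for a in range(msize):
                if final[a] != strategies[members[a]]:
                    changed = True
                    break
            if not changed:
                continue
            if pending > 0:
                for i in range(n):
                    cum[i] += cur_payoff[i] * pending
                pending = 0
            new_count = _apply_final(
                indptr, indices, strategies, old_nbrs, cur_payoff,
                members, final, msize, alpha, new_count,
            )
        pending += 1
        if check_adoption and new_count * 10 >= adopt_num:
            for i in range(n):
                cum[i] += cur_payoff[i] * pending
            return p + 1, new_count, True
    if pending > 0:
        for i in range(n):
            cum[i] += cur_payoff[i] * pending
    return periods, new_count, False
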