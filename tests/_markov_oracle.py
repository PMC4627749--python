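"""Exact Markov chain for small demes under the coalition-update dynamics.

Independent of the package's update engine: payoffs, coalition-selection
probabilities, better-response sets and mistake convolution are re-derived
here directly from the model definition, by full enumeration over the
2^n strategy configurations of a tiny graph.  Used as the oracle for
long-run occupancy tests.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product

import numpy as np


def _payoffs(adj, state, alpha):
    n = len(adj)
    out = []
    for i in range(n):
        s = (state >> i) & 1
        match = sum(1 for w in adj[i] if ((state >> w) & 1) == s)
        out.append(match * (alpha if s else 1.0) / len(adj[i]))
    return out


def coalition_distribution(adj, types, k=2, pair_prob=0.5):
    """P(coalition) under the sampling scheme, as exact fractions.

    Seed individual uniform; SI seeds with at least one SI neighbor attempt
    (probability ``pair_prob``) to grow to size 2 by absorbing a uniformly
    chosen adjacent SI individual.  Only k <= 2 is needed for the oracle.
    """
    assert k <= 2
    n = len(adj)
    dist: dict[tuple[int, ...], Fraction] = {}
    pu = Fraction(1, n)
    pp = Fraction(pair_prob).limit_denominator(10**6)
    for u in range(n):
        si_nbrs = [w for w in adj[u] if types[w]] if (k >= 2 and types[u]) else []
        if not si_nbrs:
            dist[(u,)] = dist.get((u,), Fraction(0)) + pu
            continue
        dist[(u,)] = dist.get((u,), Fraction(0)) + pu * (1 - pp)
        for w in si_nbrs:
            c = tuple(sorted((u, w)))
            dist[c] = dist.get(c, Fraction(0)) + pu * pp / len(si_nbrs)
    assert sum(dist.values()) == 1
    return dist


def _intended_distribution(adj, state, coalition, alpha):
    """Distribution over intended joint assignments for the coalition."""
    members = sorted(coalition)
    cur_pay = _payoffs(adj, state, alpha)
    current = tuple((state >> m) & 1 for m in members)
    feasible = []
    for assign in product((0, 1), repeat=len(members)):
        new_state = state
        for m, s in zip(members, assign):
            new_state = (new_state & ~(1 << m)) | (s << m)
        pays = _payoffs(adj, new_state, alpha)
        if all(pays[m] >= cur_pay[m] - 1e-12 for m in members):
            feasible.append((assign, pays))
    strict = [
        a for a, pays in feasible
        if any(pays[m] > cur_pay[m] + 1e-12 for m in members)
    ]
    if not strict:
        return {current: 1.0}
    p = 1.0 / len(strict)
    return {a: p for a in strict}


def transition_matrix(adj, types, alpha, epsilon, k=2, pair_prob=0.5):
    """Exact single-event transition matrix over the 2^n strategy states."""
    n = len(adj)
    size = 1 << n
    P = np.zeros((size, size))
    cdist = coalition_distribution(adj, types, k, pair_prob)
    for state in range(size):
        for coalition, pc in cdist.items():
            members = sorted(coalition)
            for intended, pi in _intended_distribution(
                adj, state, coalition, alpha
            ).items():
                # convolve independent mistakes: realized strategy equals the
                # intended one w.p. 1 - eps/2, flips w.p. eps/2
                for realized in product((0, 1), repeat=len(members)):
                    pr = 1.0
                    for s_int, s_real in zip(intended, realized):
                        pr *= (1 - epsilon / 2) if s_real == s_int else epsilon / 2
                    if pr == 0.0:
                        continue
                    new_state = state
                    for m, s in zip(members, realized):
                        new_state = (new_state & ~(1 << m)) | (s << m)
                    P[state, new_state] += float(pc) * pi * pr
    assert np.allclose(P.sum(axis=1), 1.0)
    return P


def stationary_distribution(P):
    """Left eigenvector of the transition matrix for eigenvalue 1."""
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()
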