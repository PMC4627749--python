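"""Within-generation dynamics: coalition sampling, better responses, adoption.

A generation consists of ``T`` periods.  Each period comprises
``updates_per_period`` coalition-update events (default ``n``, i.e. roughly
one revision opportunity per individual per period — with ``T = 2000``
periods per 20-year generation this matches a couple of revision
opportunities per individual per week).  In each event one *coalition* — a
single individual, or a small connected set of adjacent shared-intentionality
(SI) individuals — is selected to revise its strategies.  The coalition plays
a *coalitional better response*: holding everyone else fixed, it moves to a
joint strategy assignment under which every member's degree-averaged payoff
is at least as high as their current payoff (strictly higher for at least one
member, otherwise it stays put).  Each updating member then independently
commits a mistake with probability ``epsilon``, replacing their intended
strategy with a uniform random one.  At the end of every period, payoffs
are realized for *all* individuals and added to cumulative fitness, and the
deme checks the adoption rule: if at least 90% of individuals play NEW, the
deme climbs one rung of the technology ladder (``tau + 1``) and every
strategy resets to OLD.

Coalition sampling (``sample_update_coalition``) draws one individual ``u``
uniformly.  If coalitions are enabled (``k >= 2``), ``u`` is SI and has at
least one SI neighbor, then with probability ``pair_attempt_prob`` the
coalition grows from ``u`` by repeatedly absorbing a uniformly chosen SI
neighbor of the growing set, up to a uniformly drawn target size in
``{2..k}``; otherwise ``u`` updates alone.  Singletons therefore remain
frequent, N types always update alone, and multi-member coalitions are
connected sets of SI types — the only joint agency the SI trait confers.

Payoffs are cached per individual and patched incrementally when strategies
flip; the cache is exactly the degree-averaged payoff of the current profile
at all times (tests verify coherence against full recomputation).
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Sequence

from . import game
from .game import OLD, TechSchedule
from .network import Graph

__all__ = [
    "N_TYPE",
    "SI_TYPE",
    "Params",
    "DemeState",
    "GenerationStats",
    "sample_update_coalition",
    "better_response_profiles",
    "select_profile",
    "apply_mistakes",
    "run_period",
    "check_and_apply_adoption",
    "run_generation",
]

N_TYPE = 0
SI_TYPE = 1

#: fraction of a deme that must play NEW for the technology to be adopted
ADOPTION_THRESHOLD = 0.9


@dataclass(frozen=True)
class Params:
    """Immutable run configuration (benchmark values as defaults).

    ``m`` demes of ``n`` individuals interact on fresh scale-free graphs of
    mean degree ``d`` for ``T`` periods per generation; ``alpha`` is the
    payoff ratio of the coordination game (a number or a
    :class:`~demetech.game.TechSchedule`); ``k`` caps coalition size;
    ``epsilon`` is the per-update mistake rate; ``mu`` the type mutation
    rate at reproduction; ``eta`` the per-deme per-generation probability of
    facing an invader.  Variant switches: ``placebo`` disables inter-demic
    selection entirely; ``migration_rate`` is a per-individual swap
    probability applied after reproduction; ``replacement_fraction`` is the
    fraction of an invaded deme replaced by invader replicas (1.0 =
    full extinction/replacement).  ``updates_per_period`` sets the number
    of coalition-update events per period (default: one per individual);
    ``engine`` selects the generation loop ("python" reference path,
    "numba" kernel, or "auto").
    """

    m: int = 64
    n: int = 32
    d: int = 6
    alpha: object = 1.2
    T: int = 2000
    k: int = 2
    epsilon: float = 0.05
    mu: float = 0.001
    eta: float = 0.10
    placebo: bool = False
    migration_rate: float = 0.0
    replacement_fraction: float = 1.0
    p_si_init: float = 0.5
    generations: int = 500
    replicates: int = 10
    seed: int = 0
    pair_attempt_prob: float = 0.5
    carry_strategies: bool = False
    updates_per_period: int | None = None
    engine: str = "auto"
    schedule: TechSchedule = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive")
        if self.T < 0 or self.generations < 0 or self.replicates < 1:
            raise ValueError("T, generations must be >= 0; replicates >= 1")
        if self.k < 1:
            raise ValueError(f"k={self.k} must be >= 1")
        for name in ("epsilon", "mu", "eta", "migration_rate", "p_si_init",
                     "pair_attempt_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 < self.replacement_fraction <= 1.0:
            raise ValueError("replacement_fraction must lie in (0, 1]")
        if self.updates_per_period is not None and self.updates_per_period < 1:
            raise ValueError("updates_per_period must be >= 1")
        if self.engine not in ("auto", "python", "numba"):
            raise ValueError(f"engine={self.engine!r} not one of auto/python/numba")
        object.__setattr__(self, "schedule", TechSchedule.ensure(self.alpha))

    @property
    def events_per_period(self) -> int:
        """Coalition-update events per period (defaults to the deme size)."""
        return self.n if self.updates_per_period is None else self.updates_per_period


@dataclass
class GenerationStats:
    """Outcome of one deme-generation: ladder steps and final fitnesses."""

    steps: int
    cum_fitness: list[float]


class DemeState:
    """Mutable state of one deme within a generation.

    Holds the interaction graph, per-individual strategies and heritable
    types, the deme's technology level ``tau``, cumulative fitness, and a
    coherent cache of current degree-averaged payoffs.
    """

    __slots__ = (
        "graph", "strategies", "types", "tau", "cum_fitness",
        "cur_payoff", "_old_nbrs", "new_count",
    )

    def __init__(
        self,
        graph: Graph,
        types: Sequence[int],
        tau: int = 0,
        strategies: Sequence[int] | None = None,
        alpha: float | None = None,
    ) -> None:
        n = graph.n_nodes
        if len(types) != n:
            raise ValueError("types length must equal graph size")
        self.graph = graph
        self.types = list(types)
        self.tau = tau
        self.strategies = [int(OLD)] * n if strategies is None else list(strategies)
        if len(self.strategies) != n:
            raise ValueError("strategies length must equal graph size")
        self.cum_fitness = [0.0] * n
        self.cur_payoff = [0.0] * n
        self._old_nbrs = [0] * n
        self.new_count = 0
        self.refresh_payoffs(alpha if alpha is not None else 1.5)

    @property
    def n(self) -> int:
        return self.graph.n_nodes

    @property
    def si_fraction(self) -> float:
        return sum(self.types) / len(self.types)

    def refresh_payoffs(self, alpha: float) -> None:
        """Rebuild the payoff cache by full recomputation."""
        strategies = self.strategies
        nbrs = self.graph.neighbors
        self.new_count = sum(strategies)
        for i in range(self.n):
            old = sum(1 for w in nbrs[i] if strategies[w] == 0)
            self._old_nbrs[i] = old
            deg = len(nbrs[i])
            if strategies[i] == 0:
                self.cur_payoff[i] = old / deg
            else:
                self.cur_payoff[i] = alpha * (deg - old) / deg

    def reset_for_generation(
        self, graph: Graph, alpha: float, carry_strategies: bool = False
    ) -> None:
        """Fresh graph, zero fitness; strategies reset to OLD unless carried."""
        if graph.n_nodes != self.n:
            raise ValueError("replacement graph has wrong size")
        self.graph = graph
        if not carry_strategies:
            self.strategies = [0] * self.n
        self.cum_fitness = [0.0] * self.n
        self.refresh_payoffs(alpha)

    def _reset_strategies_old(self) -> None:
        # all-OLD profile: every payoff is exactly 1 (all neighbors match)
        n = self.n
        self.strategies = [0] * n
        self.new_count = 0
        degs = self.graph.degrees
        for i in range(n):
            self._old_nbrs[i] = degs[i]
            self.cur_payoff[i] = 1.0

    def payoff_cache_errors(self, alpha: float) -> float:
        """Max |cached - recomputed| payoff; 0.0 when the cache is coherent."""
        return max(
            abs(
                self.cur_payoff[i]
                - game.individual_payoff(self.graph, self.strategies, i, alpha)
            )
            for i in range(self.n)
        )


# ---------------------------------------------------------------------------
# coalition sampling


def sample_update_coalition(
    deme: DemeState, k: int, rng: random.Random, pair_attempt_prob: float = 0.5
) -> tuple[int, ...]:
    """Select the updating coalition for one period (sorted member tuple)."""
    n = deme.n
    u = rng.randrange(n)
    if k < 2 or deme.types[u] != SI_TYPE:
        return (u,)
    types = deme.types
    nbrs = deme.graph.neighbors
    si_nbrs = [w for w in nbrs[u] if types[w] == SI_TYPE]
    if not si_nbrs or rng.random() >= pair_attempt_prob:
        return (u,)
    target = 2 if k == 2 else rng.randrange(2, k + 1)
    members = [u]
    mset = {u}
    cands = si_nbrs
    while len(members) < target:
        w = cands[rng.randrange(len(cands))]
        members.append(w)
        mset.add(w)
        if len(members) == target:
            break
        cands = sorted(
            {x for mm in members for x in nbrs[mm]
             if types[x] == SI_TYPE and x not in mset}
        )
        if not cands:
            break
    return tuple(sorted(members))


# ---------------------------------------------------------------------------
# better response


def better_response_profiles(
    deme: DemeState, coalition: Sequence[int], alpha: float
) -> dict[tuple[int, ...], tuple[float, ...]]:
    """Enumerate the coalitional better responses of ``coalition``.

    Returns a mapping from each feasible joint strategy assignment (a tuple
    over the sorted coalition members) to the member payoffs it yields,
    holding all non-members fixed.  An assignment is feasible when *every*
    member's payoff under it is at least their current payoff; the current
    assignment is always included.
    """
    members = tuple(sorted(coalition))
    c = len(members)
    strategies = deme.strategies
    nbrs = deme.graph.neighbors
    pos = {m: idx for idx, m in enumerate(members)}
    ext_old = []
    int_adj = []
    degs = []
    current = tuple(strategies[m] for m in members)
    cur_pay = tuple(deme.cur_payoff[m] for m in members)
    for m in members:
        adj_in = [pos[w] for w in nbrs[m] if w in pos]
        eo = sum(1 for w in nbrs[m] if w not in pos and strategies[w] == 0)
        int_adj.append(adj_in)
        ext_old.append(eo)
        degs.append(len(nbrs[m]))
    out: dict[tuple[int, ...], tuple[float, ...]] = {}
    for assign in itertools.product((0, 1), repeat=c):
        pays = []
        ok = True
        for idx in range(c):
            internal_old = sum(1 for j in int_adj[idx] if assign[j] == 0)
            if assign[idx] == 0:
                p = (ext_old[idx] + internal_old) / degs[idx]
            else:
                ext_new = degs[idx] - len(int_adj[idx]) - ext_old[idx]
                internal_new = len(int_adj[idx]) - internal_old
                p = alpha * (ext_new + internal_new) / degs[idx]
            if p < cur_pay[idx] and assign != current:
                ok = False
                break
            pays.append(p)
        if ok:
            out[assign] = tuple(pays)
    return out


def select_profile(
    profiles: dict[tuple[int, ...], tuple[float, ...]],
    current: tuple[int, ...],
    rng: random.Random,
) -> tuple[int, ...]:
    """Pick the intended assignment among the feasible better responses.

    If any feasible assignment makes at least one member *strictly* better
    off, one such assignment is chosen uniformly at random; otherwise the
    coalition keeps its current strategies.  (The random stream is consumed
    only when two or more strict improvements tie.)
    """
    cur_pay = profiles[current]
    strict = [
        a
        for a, pays in profiles.items()
        if any(p > q for p, q in zip(pays, cur_pay))
    ]
    if not strict:
        return current
    if len(strict) == 1:
        return strict[0]
    return strict[rng.randrange(len(strict))]


def apply_mistakes(
    intended: tuple[int, ...], epsilon: float, rng: random.Random
) -> tuple[int, ...]:
    """Independently per member: with probability ``epsilon`` replace the
    intended strategy by a uniform draw from {OLD, NEW}."""
    if epsilon == 0.0:
        return intended
    out = []
    for s in intended:
        if rng.random() < epsilon:
            out.append(0 if rng.random() < 0.5 else 1)
        else:
            out.append(s)
    return tuple(out)


# ---------------------------------------------------------------------------
# period loop


def _propose_update(
    deme: DemeState,
    alpha: float,
    k: int,
    epsilon: float,
    pair_attempt_prob: float,
    rng: random.Random,
) -> list[tuple[int, int]]:
    """One period's strategy revision, *not yet applied*.

    Samples a coalition, computes its intended coalitional better response,
    applies mistakes, and returns the list of ``(node, new_strategy)`` flips
    relative to the current profile.  Fast inline paths cover the singleton
    and pair cases that dominate the benchmark (``k = 2``); larger
    coalitions fall back to full enumeration.  Both paths consume the random
    stream identically to the public operations they mirror.
    """
    members = sample_update_coalition(deme, k, rng, pair_attempt_prob)
    strategies = deme.strategies
    nbrs = deme.graph.neighbors

    if len(members) == 1:
        (i,) = members
        adj = nbrs[i]
        deg = len(adj)
        old = deme._old_nbrs[i]
        p_old = old / deg
        p_new = alpha * (deg - old) / deg
        s_i = strategies[i]
        # switch only on strict improvement; ties retain the current strategy
        if s_i == 0:
            intended = (1,) if p_new > p_old else (0,)
        else:
            intended = (0,) if p_old > p_new else (1,)
    elif len(members) == 2:
        i, j = members
        adj_i, adj_j = nbrs[i], nbrs[j]
        deg_i, deg_j = len(adj_i), len(adj_j)
        s_i, s_j = strategies[i], strategies[j]
        # external old-neighbor counts (exclude the partner)
        eo_i = deme._old_nbrs[i] - (1 - s_j)
        eo_j = deme._old_nbrs[j] - (1 - s_i)
        en_i = deg_i - 1 - eo_i
        en_j = deg_j - 1 - eo_j
        cur_i = deme.cur_payoff[i]
        cur_j = deme.cur_payoff[j]
        current = (s_i, s_j)
        # enumerate the four assignments in lexicographic order
        strict = []
        for a_i, a_j in ((0, 0), (0, 1), (1, 0), (1, 1)):
            if a_i == 0:
                p_i = (eo_i + (1 if a_j == 0 else 0)) / deg_i
            else:
                p_i = alpha * (en_i + (1 if a_j == 1 else 0)) / deg_i
            if p_i < cur_i:
                continue
            if a_j == 0:
                p_j = (eo_j + (1 if a_i == 0 else 0)) / deg_j
            else:
                p_j = alpha * (en_j + (1 if a_i == 1 else 0)) / deg_j
            if p_j < cur_j:
                continue
            if p_i > cur_i or p_j > cur_j:
                strict.append((a_i, a_j))
        if not strict:
            intended = current
        elif len(strict) == 1:
            intended = strict[0]
        else:
            intended = strict[rng.randrange(len(strict))]
    else:
        profiles = better_response_profiles(deme, members, alpha)
        current = tuple(strategies[m] for m in members)
        intended = select_profile(profiles, current, rng)

    if epsilon > 0.0:
        final = []
        for s in intended:
            if rng.random() < epsilon:
                final.append(0 if rng.random() < 0.5 else 1)
            else:
                final.append(s)
    else:
        final = intended
    return [
        (m, s) for m, s in zip(members, final) if s != strategies[m]
    ]


def _apply_changes(
    deme: DemeState, changes: list[tuple[int, int]], alpha: float
) -> None:
    """Flip strategies and patch the payoff cache of the affected closure."""
    strategies = deme.strategies
    old_nbrs = deme._old_nbrs
    nbrs = deme.graph.neighbors
    affected = set()
    for i, s in changes:
        delta = -1 if s == 1 else 1  # node leaves/enters the OLD camp
        strategies[i] = s
        deme.new_count += 1 if s == 1 else -1
        affected.add(i)
        for w in nbrs[i]:
            old_nbrs[w] += delta
            affected.add(w)
    cur = deme.cur_payoff
    degs = deme.graph.degrees
    for i in affected:
        deg = degs[i]
        if strategies[i] == 0:
            cur[i] = old_nbrs[i] / deg
        else:
            cur[i] = alpha * (deg - old_nbrs[i]) / deg


def check_and_apply_adoption(deme: DemeState) -> bool:
    """Climb the ladder when >= 90% of the deme plays NEW.

    On adoption ``tau`` increments and every strategy resets to OLD (the
    innovation becomes the new status quo).  The 90% boundary is inclusive
    and evaluated exactly in integer arithmetic.
    """
    if deme.new_count * 10 >= deme.n * 9:
        deme.tau += 1
        deme._reset_strategies_old()
        return True
    return False


def run_period(deme: DemeState, params: Params, rng: random.Random) -> bool:
    """Execute one period: ``events_per_period`` coalition updates, then
    payoff realization for all individuals, then the adoption check.

    Returns True when the period ended with a technology adoption.
    """
    alpha = params.schedule.alpha_for(deme.tau)
    for _ in range(params.events_per_period):
        changes = _propose_update(
            deme, alpha, params.k, params.epsilon, params.pair_attempt_prob, rng
        )
        if changes:
            _apply_changes(deme, changes, alpha)
    cum = deme.cum_fitness
    cur = deme.cur_payoff
    for i in range(deme.n):
        cum[i] += cur[i]
    return check_and_apply_adoption(deme)


def _run_generation_python(
    deme: DemeState, params: Params, rng: random.Random
) -> int:
    """Reference generation loop; exactly equivalent to composing
    :func:`run_period` ``T`` times on the same random stream (fitness
    accrual is batched across change-free periods)."""
    n = deme.n
    events = params.events_per_period
    k = params.k
    eps = params.epsilon
    pap = params.pair_attempt_prob
    schedule = params.schedule
    alpha = schedule.alpha_for(deme.tau)
    cum = deme.cum_fitness
    steps = 0
    pending = 0  # completed periods not yet accrued (payoffs unchanged since)
    adopt_num = n * 9  # adoption iff 10*new_count >= 9*n
    for _t in range(params.T):
        for _e in range(events):
            changes = _propose_update(deme, alpha, k, eps, pap, rng)
            if not changes:
                continue
            if pending > 0:
                cur = deme.cur_payoff
                for i in range(n):
                    cum[i] += cur[i] * pending
                pending = 0
            _apply_changes(deme, changes, alpha)
        pending += 1
        if deme.new_count * 10 >= adopt_num:
            cur = deme.cur_payoff
            for i in range(n):
                cum[i] += cur[i] * pending
            pending = 0
            deme.tau += 1
            steps += 1
            deme._reset_strategies_old()
            alpha = schedule.alpha_for(deme.tau)
    if pending > 0:
        cur = deme.cur_payoff
        for i in range(n):
            cum[i] += cur[i] * pending
    return steps


def _run_generation_numba(
    deme: DemeState, params: Params, rng: random.Random
) -> int:
    """Array-based generation loop on the numba kernel (same semantics as
    the reference path; distinct random stream, seeded from ``rng``)."""
    import numpy as np

    from . import _kernel

    indptr, indices = deme.graph.csr()
    strategies = np.asarray(deme.strategies, dtype=np.int64)
    types = np.asarray(deme.types, dtype=np.int64)
    old_nbrs = np.asarray(deme._old_nbrs, dtype=np.int64)
    cur_payoff = np.asarray(deme.cur_payoff, dtype=np.float64)
    cum = np.asarray(deme.cum_fitness, dtype=np.float64)
    degrees = np.asarray(deme.graph.degrees, dtype=np.int64)
    schedule = params.schedule
    alpha = schedule.alpha_for(deme.tau)
    _kernel.seed_kernel_rng(rng.getrandbits(31))
    steps = 0
    new_count = deme.new_count
    periods_left = params.T
    while periods_left > 0:
        done, new_count, adopted = _kernel.run_segment(
            indptr, indices, strategies, types, old_nbrs, cur_payoff, cum,
            new_count, alpha, periods_left, params.events_per_period,
            params.k, params.epsilon, params.pair_attempt_prob, True,
        )
        periods_left -= done
        if adopted:
            deme.tau += 1
            steps += 1
            strategies[:] = 0
            old_nbrs[:] = degrees
            cur_payoff[:] = 1.0
            new_count = 0
            alpha = schedule.alpha_for(deme.tau)
    deme.strategies = [int(s) for s in strategies]
    deme._old_nbrs = [int(o) for o in old_nbrs]
    deme.cur_payoff = [float(p) for p in cur_payoff]
    deme.cum_fitness = [float(c) for c in cum]
    deme.new_count = int(new_count)
    return steps


def run_generation(
    deme: DemeState, params: Params, rng: random.Random
) -> GenerationStats:
    """Run ``T`` periods on a prepared deme and count ladder steps.

    The caller is responsible for drawing a fresh graph and resetting
    strategies/fitness (see :meth:`DemeState.reset_for_generation`).  With
    ``params.engine = "python"`` this composes the reference period loop;
    the default (``"auto"``) uses the compiled kernel when numba is
    available — identical update semantics, but an independent random
    stream, so trajectories are reproducible per engine, not across
    engines.
    """
    engine = params.engine
    if engine == "auto":
        from ._kernel import HAVE_NUMBA

        engine = "numba" if HAVE_NUMBA else "python"
    if engine == "numba":
        steps = _run_generation_numba(deme, params, rng)
    else:
        steps = _run_generation_python(deme, params, rng)
    return GenerationStats(steps=steps, cum_fitness=list(deme.cum_fitness))
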