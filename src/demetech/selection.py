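"""End-of-generation selection: deme extinction/invasion and reproduction.

Inter-demic selection is keyed purely on technology: each generation, with
probability ``eta``, a deme faces an invader drawn uniformly from the other
demes.  A lower-technology invader is repelled; a higher-technology invader
replaces the invaded deme with a replica of itself (types, cumulative
payoffs and technology level); equal technology is decided by a fair coin.
All invasions in a generation are evaluated against a snapshot of the
pre-stage metapopulation, so outcomes are independent of processing order
and a deme replaced this stage still invades elsewhere with its snapshot.

Within demes, reproduction follows a finite-population replicator dynamic:
each of ``n`` offspring independently picks a parent with probability
proportional to the parent's cumulative fitness over the generation and
inherits the parent's type, flipped with mutation probability ``mu``.
Reproduction alone never selects on type beyond fitness differences accrued
within the deme; drift does the rest.

Two robustness variants are provided: per-individual migration (type swaps
between demes, conserving deme sizes) and partial replacement (only a
fraction ``rho`` of an invaded deme is replaced by invader replicas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import DemeState

__all__ = [
    "Metapopulation",
    "InvasionEvent",
    "InvasionLog",
    "extinction_stage",
    "reproduce_deme",
    "reproduction_stage",
    "migration_stage",
    "partial_replacement",
]


@dataclass
class Metapopulation:
    """``m`` demes plus a generation counter; sizes are fixed for a run."""

    demes: list[DemeState]
    generation: int = 0

    @property
    def m(self) -> int:
        return len(self.demes)


@dataclass(frozen=True)
class InvasionEvent:
    generation: int
    invaded: int
    invader: int
    outcome: str  # repelled | replaced | coin-replaced | coin-repelled


@dataclass
class InvasionLog:
    """At most one invasion event per invaded deme per generation."""

    events: list[InvasionEvent] = field(default_factory=list)

    def append(self, ev: InvasionEvent) -> None:
        self.events.append(ev)

    def __len__(self) -> int:
        return len(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.generation, e.invaded, e.invader, e.outcome)
                for e in self.events
            ],
            columns=["generation", "invaded", "invader", "outcome"],
        )


@dataclass(frozen=True)
class _DemeSnapshot:
    """Pre-stage replica source: heritable types, payoffs and technology."""

    tau: int
    types: tuple[int, ...]
    cum_fitness: tuple[float, ...]


def _snapshot(deme: DemeState) -> _DemeSnapshot:
    return _DemeSnapshot(deme.tau, tuple(deme.types), tuple(deme.cum_fitness))


def partial_replacement(
    invaded: DemeState,
    invader_snapshot,
    rho: float,
    rng: np.random.Generator,
) -> DemeState:
    """Replace a round(rho*n) subset of the invaded deme by invader replicas.

    A uniformly chosen subset of the invaded deme's individuals is replaced
    by replicas (type and cumulative payoff) of a uniformly chosen same-size
    subset of the invader's snapshot; the invaded deme's technology level
    becomes the invader's (the invasion succeeded).  ``rho = 1`` reduces
    exactly to full replacement.  Modifies ``invaded`` in place and returns
    it.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho={rho} must lie in (0, 1]")
    n = invaded.n
    count = int(round(rho * n))
    if count >= n:
        invaded.types = list(invader_snapshot.types)
        invaded.cum_fitness = list(invader_snapshot.cum_fitness)
    else:
        dst = rng.choice(n, size=count, replace=False)
        src = rng.choice(len(invader_snapshot.types), size=count, replace=False)
        for a, b in zip(dst, src):
            invaded.types[a] = invader_snapshot.types[b]
            invaded.cum_fitness[a] = invader_snapshot.cum_fitness[b]
    invaded.tau = invader_snapshot.tau
    return invaded


def extinction_stage(
    pop: Metapopulation,
    eta: float,
    rng: np.random.Generator,
    replacement_fraction: float = 1.0,
) -> tuple[Metapopulation, InvasionLog]:
    """Inter-demic invasion/replacement, evaluated against a snapshot.

    Independently for each deme with probability ``eta``, a uniform random
    *other* deme invades.  Higher snapshot technology replaces the invaded
    deme (fully, or partially when ``replacement_fraction < 1``); lower is
    repelled; ties are decided by a fair coin.  Modifies ``pop`` in place.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta={eta} must lie in [0, 1]")
    log = InvasionLog()
    m = pop.m
    if m < 2:
        if eta > 0.0:
            warnings.warn("extinction stage skipped: need at least 2 demes")
        return pop, log
    snaps = [_snapshot(d) for d in pop.demes]
    for i in range(m):
        if rng.random() >= eta:
            continue
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        inv, cur = snaps[j], snaps[i]
        if inv.tau < cur.tau:
            outcome = "repelled"
        elif inv.tau > cur.tau:
            outcome = "replaced"
        else:
            outcome = "coin-replaced" if rng.random() < 0.5 else "coin-repelled"
        if outcome in ("replaced", "coin-replaced"):
            partial_replacement(pop.demes[i], inv, replacement_fraction, rng)
        log.append(InvasionEvent(pop.generation, i, j, outcome))
    return pop, log


def reproduce_deme(
    cum_fitness: Sequence[float],
    types: Sequence[int],
    mu: float,
    n: int,
    rng: np.random.Generator,
) -> list[int]:
    """Draw ``n`` offspring types by fitness-proportional parent sampling.

    Each offspring independently picks parent ``i`` with probability
    ``fitness_i / sum(fitness)`` and inherits the parent's type, flipped
    with probability ``mu``.  When total fitness is zero, parents are drawn
    uniformly (degenerate-input fallback).
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu={mu} must lie in [0, 1]")
    w = np.asarray(cum_fitness, dtype=float)
    if np.any(w < 0):
        raise ValueError("fitness must be non-negative")
    total = w.sum()
    if total > 0:
        parents = rng.choice(len(w), size=n, p=w / total)
    else:
        parents = rng.integers(len(w), size=n)
    offspring = np.asarray(types, dtype=np.int64)[parents]
    flips = rng.random(n) < mu
    offspring = np.where(flips, 1 - offspring, offspring)
    return [int(t) for t in offspring]


def reproduction_stage(
    pop: Metapopulation, mu: float, rng: np.random.Generator
) -> Metapopulation:
    """Apply :func:`reproduce_deme` to every deme; technology carries over."""
    for deme in pop.demes:
        deme.types = reproduce_deme(deme.cum_fitness, deme.types, mu, deme.n, rng)
    return pop


def migration_stage(
    pop: Metapopulation, migration_rate: float, rng: np.random.Generator
) -> Metapopulation:
    """Swap each individual's type with a random individual elsewhere,
    independently with probability ``migration_rate``; deme sizes and the
    global type counts are conserved."""
    if not 0.0 <= migration_rate <= 1.0:
        raise ValueError(f"migration_rate={migration_rate} must lie in [0, 1]")
    m = pop.m
    if migration_rate == 0.0 or m < 2:
        return pop
    for d in range(m):
        deme = pop.demes[d]
        for i in range(deme.n):
            if rng.random() >= migration_rate:
                continue
            o = int(rng.integers(m - 1))
            if o >= d:
                o += 1
            other = pop.demes[o]
            j = int(rng.integers(other.n))
            deme.types[i], other.types[j] = other.types[j], deme.types[i]
    return pop
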