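"""Orchestration of the generation cycle across demes and replicates.

Each generation of a run proceeds deme by deme: (a) a fresh interaction
graph is drawn for every deme, strategies reset to the status-quo OLD and
fitness to zero; (b) the within-generation period dynamics run
(:func:`~demetech.dynamics.run_generation`), accruing fitness and possibly
climbing the technology ladder; (c) inter-demic extinction/invasion (skipped
in placebo runs); (d) fitness-proportional reproduction with mutation, plus
optional migration; (e) technology levels and type counts carry forward.

Replicate ``r`` uses master seed ``params.seed + r``; per-deme random
streams and the population-level stream are spawned deterministically from
it, so a run is exactly reproducible from ``(Params, seed)`` and deme
trajectories do not depend on scheduling order.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DemeState, Params, SI_TYPE, run_generation
from .network import generate_interaction_graph
from .selection import (
    Metapopulation,
    extinction_stage,
    migration_stage,
    reproduction_stage,
)

__all__ = [
    "SimulationRecord",
    "init_metapopulation",
    "run_simulation",
    "summarize_si",
    "summarize_tech_rate",
]

RECORD_COLUMNS = ["replicate", "generation", "deme", "si_fraction", "tau", "steps"]


@dataclass
class SimulationRecord:
    """Tidy per-(replicate, generation, deme) trajectory of a run.

    ``data`` has one row per deme per recorded generation (generation 0 is
    the initial state) with columns ``replicate, generation, deme,
    si_fraction, tau, steps``; ``invasions`` logs every invasion event with
    its outcome.
    """

    data: pd.DataFrame
    invasions: pd.DataFrame
    params: Params
    seed: int

    def write_csv(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(out / "record.csv", index=False)
        self.invasions.to_csv(out / "invasions.csv", index=False)
        meta = {
            f: getattr(self.params, f)
            for f in self.params.__dataclass_fields__
            if f != "schedule"
        }
        meta["alpha"] = _alpha_repr(meta["alpha"])
        with open(out / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def _alpha_repr(alpha) -> object:
    try:
        return float(alpha)
    except (TypeError, ValueError):
        return repr(alpha)


def init_metapopulation(
    params: Params,
    rng: np.random.Generator,
    graph_rngs: list[random.Random] | None = None,
) -> Metapopulation:
    """Create ``m`` demes at technology 0, all strategies OLD, zero fitness.

    Each individual is independently SI with probability ``params.p_si_init``
    (drawn from ``rng``); graphs are drawn from ``graph_rngs`` when given
    (one stream per deme slot), else from streams seeded off ``rng``.
    """
    alpha0 = params.schedule.alpha_for(0)
    demes = []
    for d_idx in range(params.m):
        if graph_rngs is not None:
            grng = graph_rngs[d_idx]
        else:
            grng = random.Random(int(rng.integers(2**31)))
        graph = generate_interaction_graph(params.n, params.d, grng)
        types = [
            SI_TYPE if rng.random() < params.p_si_init else 0
            for _ in range(params.n)
        ]
        demes.append(DemeState(graph, types, tau=0, alpha=alpha0))
    return Metapopulation(demes, generation=0)


def _replicate_streams(params: Params, rep: int):
    """Spawn the replicate's deterministic random streams."""
    ss = np.random.SeedSequence(params.seed + rep)
    init_ss, pop_ss, *deme_ss = ss.spawn(2 + params.m)
    init_rng = np.random.default_rng(init_ss)
    pop_rng = np.random.default_rng(pop_ss)
    deme_rngs = [
        random.Random(int(np.random.default_rng(s).integers(2**62)))
        for s in deme_ss
    ]
    return init_rng, pop_rng, deme_rngs


def run_simulation(params: Params) -> SimulationRecord:
    """Run the full multilevel simulation; reproducible from ``(Params, seed)``."""
    rows: list[tuple] = []
    inv_rows: list[tuple] = []
    for rep in range(params.replicates):
        init_rng, pop_rng, deme_rngs = _replicate_streams(params, rep)
        pop = init_metapopulation(params, init_rng, graph_rngs=deme_rngs)
        for d_idx, deme in enumerate(pop.demes):
            rows.append((rep, 0, d_idx, deme.si_fraction, deme.tau, 0))
        for gen in range(1, params.generations + 1):
            pop.generation = gen
            steps = []
            for d_idx, deme in enumerate(pop.demes):
                grng = deme_rngs[d_idx]
                graph = generate_interaction_graph(params.n, params.d, grng)
                deme.reset_for_generation(
                    graph,
                    params.schedule.alpha_for(deme.tau),
                    params.carry_strategies,
                )
                stats = run_generation(deme, params, grng)
                steps.append(stats.steps)
            if not params.placebo and params.eta > 0:
                pop, log = extinction_stage(
                    pop, params.eta, pop_rng, params.replacement_fraction
                )
                inv_rows.extend(
                    (rep, e.generation, e.invaded, e.invader, e.outcome)
                    for e in log.events
                )
            reproduction_stage(pop, params.mu, pop_rng)
            if params.migration_rate > 0:
                migration_stage(pop, params.migration_rate, pop_rng)
            for d_idx, deme in enumerate(pop.demes):
                rows.append(
                    (rep, gen, d_idx, deme.si_fraction, deme.tau, steps[d_idx])
                )
    data = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    invasions = pd.DataFrame(
        inv_rows,
        columns=["replicate", "generation", "invaded", "invader", "outcome"],
    )
    return SimulationRecord(data, invasions, params, params.seed)


def _window_slice(record, window) -> pd.DataFrame:
    data = record.data if isinstance(record, SimulationRecord) else record
    lo, hi = window
    sel = data[(data["generation"] >= lo) & (data["generation"] <= hi)]
    if sel.empty:
        raise ValueError(f"window {window} selects no recorded generations")
    return sel


def summarize_si(record, window) -> tuple[float, float]:
    """Pooled mean and standard deviation of the SI fraction.

    Pools over all demes, all generations in the inclusive ``window = (lo,
    hi)``, and all replicates; the standard deviation is the sample sd
    (ddof=1; zero for a single pooled value).
    """
    vals = _window_slice(record, window)["si_fraction"].to_numpy()
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def summarize_tech_rate(record, window) -> float:
    """Mean technology-ladder steps per generation per deme in the window."""
    return float(_window_slice(record, window)["steps"].mean())
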