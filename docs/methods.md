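# Methods

`demetech` simulates the joint evolution of a heritable cognitive trait —
the ability to *share intentions* with a partner — and cumulative
technological culture, in a metapopulation of small social groups (demes).
This note documents the model, its parameters, the numerical choices made
where the design was genuinely open, and the limits of what the test suite
demonstrates.

## Model

**Metapopulation.** `m` demes of fixed size `n`. Each individual carries a
heritable binary type: `SI` (can form joint intentions with an adjacent SI
partner) or `N` (revises behavior only individually). Time is divided into
generations; individuals live one generation.

**Social network.** At the start of every generation each deme draws a fresh
interaction graph: undirected, simple, connected, scale-free, with mean
degree `d`. Construction: preferential attachment seeded with a complete
graph on `d/2 + 1` nodes; each joining node attaches to either 2 or `d - 2`
distinct existing nodes (exactly half of the joiners use each count, in
random order), targets drawn with probability proportional to current
degree. This pins the edge count (mean degree within a few percent of `d`
every draw), guarantees connectivity and a minimum degree of 2, and gives
the heavy-tailed degree distribution of scale-free social networks. The
minimum degree of 2 is deliberate: real social networks of mean degree 4–8
have a periphery of weakly connected individuals, and it is through that
periphery that *marginally* profitable innovations first gain a foothold. A
construction whose least-connected members already have `d/2 ≥ 3` contacts
leaves low-premium innovations with no viable point of entry at realistic
mistake rates, freezing the low-`α` regime entirely.

**Within-deme game.** Each individual plays `OLD` or `NEW`. Along every
edge, matching on OLD pays 1, matching on NEW pays `α > 1`, miscoordination
pays 0; an individual's period payoff is the average over their neighbors.
`α` is the relative fitness premium of the next technology rung and may in
principle depend on the deme's current level `τ` (`TechSchedule`); all
shipped experiments use a constant `α`.

**Revision dynamics.** A generation comprises `T` periods. Each period
consists of `updates_per_period` coalition-update events (default `n`, i.e.
roughly one revision opportunity per individual per period; with `T = 2000`
periods per 20-year generation this corresponds to about two revision
opportunities per individual per week). Per event:

1. *Coalition sampling.* One individual `u` is drawn uniformly. If
   coalitions are enabled (`k ≥ 2`), `u` is SI and has an SI neighbor, then
   with probability `pair_attempt_prob` (default 0.5) the coalition grows
   from `u` by repeatedly absorbing a uniformly chosen SI neighbor of the
   growing set up to a uniformly drawn target size in `{2..k}`; otherwise
   `u` revises alone. N types always revise alone.
2. *Coalitional better response.* Among the `2^|C|` joint assignments
   (others held fixed), the feasible set contains those giving every member
   at least their current payoff. If any feasible assignment makes some
   member strictly better off, one is chosen uniformly among those strict
   improvements; otherwise the coalition keeps its strategies. (Ties never
   trigger payoff-neutral drift.)
3. *Mistakes.* Each member independently, with probability `ε`, replaces
   their intended strategy by a uniform draw from {OLD, NEW} — so the
   realized deviation rate per member is `ε/2`.

At the end of each period every individual's current payoff is added to
their cumulative fitness, and the deme checks the **adoption rule**: if at
least 90% of members play NEW (inclusive boundary, evaluated in integer
arithmetic — 29 of 32 is the smallest triggering count), the deme's level
becomes `τ + 1` and all strategies reset to OLD (the innovation is the new
status quo). Strategies also reset to OLD at the start of each generation.

**Inter-demic selection.** At generation end, each deme independently with
probability `η` faces an invader drawn uniformly from the other demes,
resolved against a pre-stage snapshot (no within-stage cascades; a deme
replaced this stage still invades elsewhere with its snapshot). Lower
invader technology → repelled; higher → the invaded deme is replaced by a
replica of the invader (types, cumulative payoffs, technology); equal → a
fair coin. Variant: `replacement_fraction ρ < 1` replaces only a uniformly
chosen `round(ρn)` subset by replicas of an invader subset (the technology
level still transfers).

**Reproduction.** Each deme independently draws `n` offspring; each picks a
parent with probability proportional to cumulative fitness (uniform
fallback when total fitness is zero) and inherits the parent's type,
flipped with mutation probability `μ`. Asexual, haploid. Optional
migration afterwards: each individual independently with probability
`migration_rate` swaps types with a uniform individual of a uniform other
deme (conserves deme sizes and global type counts).

## Why the two effects arise

A lone innovator surrounded by traditionalists earns nothing from its NEW
play and reverts when it next revises; clusters of innovators can be
*locked* (each member has enough NEW neighbors to stay). Shared
intentionality changes which configurations are reachable:

- **Conservative effect (low `α`).** A mutually supporting NEW pair whose
  members would each lose by reverting alone can revert *jointly* whenever
  `α ≤ 2` on path-like neighborhoods (each trades `α/2` for 1). SI demes
  therefore keep dismantling the locked clusters that mistake-driven
  cascades need as stepping stones, and climb the ladder more slowly.
- **Reforming effect (high `α`).** An OLD pair with some outside NEW
  support can jointly switch when no member could profitably switch alone
  (on the 6-node fixture: `2α/3 > 2/3` for every `α > 1`, while the lone
  switch needs `α > 2`). SI demes nucleate and spread innovations faster.

Which effect wins flips with `α`, and inter-demic selection keyed on
technology translates that into selection on the SI trait itself — the
phase transition.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| `m` | demes | 64 | scaled experiments use 16 |
| `n` | deme size | 32 | effective (≈ one-third census) band size |
| `d` | mean degree | 6 | range 4–8 |
| `α` | innovation premium | — | phase threshold lies between 1.2 and 2.2 |
| `T` | periods/generation | 2000 | ≈ 2 revision opportunities/individual/week over 20 years |
| `updates_per_period` | events/period | `n` | see "Update budget" below |
| `k` | max coalition size | 2 | pairs; 3–4 supported |
| `ε` | mistake rate | 0.05 | one mistake per 20 revisions |
| `μ` | mutation rate | 0.001 | per birth |
| `η` | invasion probability | 0.10 | per deme per generation |
| `pair_attempt_prob` | coalition attempt rate | 0.5 | sampling-scheme knob |
| `migration_rate` | swap probability | 0 | robustness variant |
| `replacement_fraction` | invaded fraction replaced | 1.0 | robustness variant |

**Update budget.** The period count `T = 2000` is calibrated as roughly two
revision opportunities per individual per week over a 20-year generation —
a *per-individual* budget. The package therefore schedules `n` coalition
events per period (~1 opportunity per individual per period). This matters
scientifically: low-premium (`α ≈ 1.2`) adoption is a rare-event cascade
that needs on the order of 10⁴–10⁵ revisions per deme-generation to
assemble; with only one event per period the low-`α` regime freezes
completely (no adoption, hence no differential deme success and no
selection on SI). `updates_per_period` is exposed for sensitivity analysis.

## Numerical and engineering choices

- **Two engines, one semantics.** The reference implementation is plain
  Python (`run_period`, and the public operations it composes); the default
  engine is a numba kernel with identical update semantics operating on CSR
  adjacency. The Python generation loop is *exactly* the composition of
  `run_period` (same random stream; fitness accrual batched across
  change-free periods, so sums agree to float re-association only). The
  kernel uses its own random stream, so trajectories are reproducible per
  engine, not across engines; both engines are validated against the exact
  stationary distribution of an independently enumerated 16-state Markov
  chain on a path fixture (total variation < 0.02 at 10⁶ events; measured
  ≈ 0.002).
- **Payoff caching.** Per-individual payoffs are cached and patched over
  the changed node's closed neighborhood on every flip; tests assert the
  cache equals full recomputation along noisy trajectories.
- **Randomness.** One master seed per run; replicate `r` uses
  `seed + r`; per-deme streams and the population-level stream are spawned
  via `numpy.random.SeedSequence`, so deme trajectories are independent of
  scheduling order. All comparisons use exact integer arithmetic where the
  model is discrete (e.g. `10·#NEW ≥ 9n` for adoption).
- **Tie-breaking.** "At least as high" better responses admit indifferent
  moves; the implementation only moves on a strict improvement for at least
  one member, choosing uniformly among strict improvements. This avoids
  payoff-neutral random walks that the model text does not call for.
- **Degenerate inputs.** Zero total fitness → uniform parent draw; a
  single-deme metapopulation skips the extinction stage with a warning;
  `T = 0` and `generations = 0` are valid no-ops.

## Scaled experiment sizes

The shipped experiments run at desk scale: the phase-transition check uses
16 demes, 1000 periods, 150 generations and 5 replicates (end-window
generations 101–150), and the speed-reversal check uses 20 seeds × 3
generations per composition. At these sizes the qualitative results are
unambiguous (end-window SI fraction ≈ 0.04–0.13 below the threshold
vs ≈ 0.78–0.98 above it; placebo ≈ 0.47), but pooled numbers are noisier
than full-scale runs (64 demes × 500 generations × 10 replicates), which
remain reachable through the CLI for anyone willing to spend the CPU time.

## What the synthetic conditions do not show

All inputs are generated by the model itself; there is no empirical data.
The fixtures (4-node path, 6-node reforming example) are synthetic
constructions chosen for exactly computable thresholds, not measured social
networks. Real social structure is clustered, assortative and temporally
persistent, whereas demes here redraw an uncorrelated scale-free graph each
generation; real technology ladders have heterogeneous rung premia, whereas
the default schedule is a constant `α`. The phase threshold's *location*
depends on graph structure (the path/6-node thresholds at `α = 2` are
fixture-specific); only the existence and direction of the two phases is
asserted. Deme extinction as full replacement is a stylization; the partial
replacement and migration variants soften but do not remove it.
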