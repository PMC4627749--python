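# demetech

An agent-based simulator of gene–culture coevolution for researchers in
evolutionary dynamics, cultural evolution and behavioral game theory. It
models how the heritable ability to *share intentions* — to revise behavior
jointly with a partner rather than alone — coevolves with cumulative
technological culture in a metapopulation of small social groups.

## The model

A metapopulation holds `m` demes of `n` individuals. Each generation, every
deme draws a fresh scale-free interaction graph of mean degree `d`, and its
members play a 2×2 coordination game along every edge: matching on the
established technology (`old`) pays 1, matching on an innovation (`new`)
pays `α > 1`, miscoordination pays 0; an individual's period payoff is the
average over neighbors. Over `T` periods per generation, randomly selected
individuals — or pairs of adjacent carriers of the *shared intentionality*
(SI) trait — play coalitional better responses, occasionally making
mistakes with probability `ε`. When ≥ 90% of a deme plays `new`, the deme
climbs one rung of its technology ladder (`τ ← τ + 1`) and the innovation
becomes the new status quo. Demes then compete: with probability `η` a deme
is challenged by a random other deme and is replaced by a replica of any
challenger with strictly higher `τ` (fair coin on ties). Finally each deme
reproduces by a finite-population replicator dynamic with mutation rate
`μ`: offspring pick parents in proportion to cumulative fitness and inherit
their type (SI or N).

Joint revision is mutualistic — both partners must gain — yet whether it
helps a deme depends on the innovation premium `α`. Pairs can coordinate
profitable joint *reversions* of innovation clusters that no individual
would abandon alone (`α` low: the conservative effect) or profitable joint
*adoptions* that no individual would risk alone (`α` high: the reforming
effect). Technology-keyed competition between demes turns that difference
in adoption speed into selection on the SI trait itself, producing a sharp
phase transition in `α` between an N-dominant, slowly innovating phase and
an SI-dominant, rapidly innovating phase.

## Worked example

```python
import demetech as dt

params = dt.Params(
    m=16, n=32, d=6, alpha=2.2, T=1000, k=2, epsilon=0.05,
    mu=0.001, eta=0.10, p_si_init=0.0, generations=150,
    replicates=5, seed=20,
)
record = dt.run_simulation(params)
si_mean, si_sd = dt.summarize_si(record, window=(101, 150))
rate = dt.summarize_tech_rate(record, window=(101, 150))
print(f"end-window SI fraction: {si_mean:.3f} +- {si_sd:.3f}")
print(f"technology steps per deme-generation: {rate:.2f}")
```

Output:

```
end-window SI fraction: 0.958 +- 0.148
technology steps per deme-generation: 46.88
```

Starting from a metapopulation with *no* SI carriers at all
(`p_si_init=0`), mutation introduces the trait, SI-rich demes out-innovate
and replace their neighbors at `α = 2.2`, and by generations 101–150 the
trait holds a large majority. The same configuration at `α = 1.2` ends the
window at an SI fraction of about 0.02 with a technology rate of about
0.08 — the other side of the phase transition.

The same experiments are scriptable from the shell:

```bash
demetech run config.json --out results/
demetech sweep config.json --alpha-grid 1.2,1.7,2.2 --out results/
demetech fixtures fixtures/   # worked-example graphs + enumerated tables
```

`run` writes a tidy `record.csv` (one row per replicate × generation ×
deme: SI fraction, technology level, ladder steps), an `invasions.csv` log
and a `metadata.json` sidecar; `sweep` summarizes SI prevalence and
technology rates per `α` over an end window.

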