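# evorank

Evolutionary ranking of agents in K-player meta-games.

When many trained agents (or strategies) interact — in tournaments,
self-play leagues, or multi-agent benchmarks — the question "which agent is
best?" has no clean answer from win rates alone: interactions are often
intransitive (A beats B beats C beats A), payoffs may be asymmetric, and
more than two agents may interact at once. `evorank` ranks the agents of a
K-player normal-form (meta-)game by the long-run behaviour of an
evolutionary dynamic, rather than by a static equilibrium concept.

## The model

Each player k is a finite population of m individuals, all programmed with
a pure strategy from S^k. In the small-mutation limit the system state is a
*monomorphic profile* s = (s^1, …, s^K): at most one population ever hosts
a mutant, which either fixates or goes extinct. A lone τ-mutant in a
σ-resident population (the other populations fixed at s^{-k}) fixates with
the closed-form birth–death probability under Fermi (logistic) selection
with ranking-intensity α,

    ρ = (1 − e^{−α u}) / (1 − e^{−m α u}),   u = f(τ) − f(σ),

and ρ = 1/m for equal fitness, where fitness is the payoff tensor entry
M^k(·, s^{-k}). These fixation probabilities define a sparse Markov chain
over all ∏|S^k| pure profiles, with transition η·ρ between
single-deviation neighbours and η = 1/Σ_k(|S^k|−1). For finite α the chain
is irreducible, so it has a unique stationary distribution π; the masses
π(s) are the agents' scores, and the induced ordering is the ranking.
Because the α → ∞ limit concentrates π on the *Markov-Conley chains* — the
sink strongly connected components of the game's weakly-better-response
graph — the tool sweeps α upward exponentially until the ranking stops
changing, and independently cross-checks the resulting support against the
sink components.

For 2-player symmetric games, a single-population reduction ranks the
strategies of the shared set directly. Replicator micro-dynamics (K ≤ 2)
are included for trajectory analysis and the discrete/continuous
edge-correspondence check.

## Worked example

```python
from evorank import AlphaRank, make_canonical_game

res = AlphaRank(make_canonical_game("battle_of_sexes"), m=50).fit()
print(res.summary())
```

```
alpha-Rank results
==================
game: battle_of_sexes   mode: multi   m: 50
alpha: 1.28   converged: True   sweep steps: 8
stationary residual: 0.00e+00
MCC support contained: True   components: 2

 rank agent        score
    1 (O,O) 5.000000e-01
    1 (M,M) 5.000000e-01
    3 (O,M) 1.663682e-55
    3 (M,O) 9.596664e-83
```

The two coordination profiles of the Battle of the Sexes tie at rank 1
with score 0.5 each: the populations spend half the time in each, and
essentially none in the miscoordinated profiles. The sweep converged at
α = 1.28, and the stationary support coincides with the two singleton sink
components (both pure Nash equilibria) of the response graph. For the
cyclic Rock-Paper-Scissors game the same call reports a three-way tie at
score 1/3 — intransitive cycles survive as a group rather than being
ranked arbitrarily.

The same pipeline runs from the shell on JSON or Gambit-style `.nfg`
payoff files:

```sh
evorank run game.json --m 50 --out results/   # ranking.tsv, sweep.tsv, DOT graphs
evorank mcc game.json                          # sink components / pure Nash only
evorank demo rps                               # canonical games
```

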