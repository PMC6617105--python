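# Methods

## The macro-model

The ranking rests on a discrete-time selection–mutation process over K
finite populations of m individuals each. Under the small-mutation limit
(μ → 0) the process is observed only on monomorphic population profiles.
Within a focal population hosting a lone mutant strategy τ against
residents σ, two individuals are sampled per step and the first copies the
second with the Fermi (logistic) probability
(1 + e^{α(f_τ − f_σ)})^{-1}, where fitness equals the payoff tensor entry
against the other populations' monomorphic strategies. The induced
birth–death chain on the mutant count has the standard closed-form
absorption (fixation) probability

ρ(u) = (1 − e^{−αu}) / (1 − e^{−mαu}),  u = f_τ − f_σ,  ρ = 1/m at u = 0.

Profile-level transitions are C_ij = η·ρ for single-deviation neighbours,
with η = 1/Σ_k(|S^k|−1) so that rows are stochastic; each row has at most
1 + Σ_k(|S^k|−1) nonzeros, making C extremely sparse for many-player games
(closed form `sparsity`: 1 − |S|(1+Σ_k(|S^k|−1))/|S|², e.g. 99.54 % for
six populations of four strategies). For finite α and finite payoffs the
chain is irreducible and its unique stationary distribution π supplies the
scores. The mutation rate never appears numerically: it is an analytic
limit, which is why exactly one population deviates per transition.

Key parameters:

- **m** (population size, default 50): sets the strength of drift; the
  neutral fixation baseline is 1/m. Values of a few tens are standard for
  this family of models; results are qualitatively insensitive to m well
  before the large-m regime.
- **α** (ranking-intensity, default handled by the sweep): α = 0 is
  neutral drift (uniform π over profiles); α → ∞ recovers the
  Markov-Conley chains. The sweep starts at α₀ = 0.01 and doubles up to 40
  times, declaring convergence when the tie-aware ranking order is
  unchanged over 3 consecutive values and no stationary mass moves by more
  than 10⁻⁴. These sweep constants are configurable; the stopping rule is
  this package's own choice, since only the exponential-sweep heuristic is
  canonical.
- **stationary_tol** (default 1e-10): accepted residual ‖πᵀC − πᵀ‖_∞.
- **neutral_fitness_tol** (default 1e-12, relative): width of the
  equal-fitness branch ρ = 1/m; the closed form is continuous through
  u = 0, so this only guards floating-point noise.

## Numerical choices

- **Fixation probability.** Evaluated as expm1(−αu)/expm1(−mαu) for
  moderate exponents; for mα|u| > 30 with u < 0 it switches to a
  log-domain form exp((1−m)α|u| + log1p(−e^{−α|u|}) − log1p(−e^{−mα|u|})),
  so strong selection never overflows and results stay in [0, 1]. An
  independent brute-force oracle solves the interior birth–death linear
  system directly from the one-step probabilities; closed form and oracle
  agree to relative error 1e-8 over a grid spanning αu ∈ [−5, 5] and
  m ∈ {2, 10, 50} (tested).
- **Stationary solver.** Chains with ≤ 2048 states are solved by
  Grassmann–Taksar–Heyman (GTH) state elimination. GTH is subtraction-free
  and therefore entrywise accurate regardless of conditioning — essential
  here, because under strong selection the chain is *nearly reducible*
  (leak probabilities between coordination profiles fall to e.g. 10⁻¹¹⁰)
  and any residual-checked linear solve can return a corner of the nearly
  invariant subspace with a deceptively tiny residual. Larger chains use
  the sparse system (Cᵀ − I)π = 0 with the normalization row substituted,
  with a power-iteration fallback, and raise if the residual tolerance is
  not met — never a silent wrong answer. Unnormalized GTH masses are
  rescaled during back-substitution to avoid overflow; if they still
  overflow the chain is reported as effectively reducible.
- **Numerical reducibility.** Entries below 10⁻³⁰⁰ are treated as zero
  when strong connectivity is verified before solving. At extreme α the
  underflow of disfavoured fixation probabilities genuinely disconnects
  the chain in double precision (e.g. the two-population Battle of the
  Sexes at α = 10, where the leak is e^{−980}); the solver raises an
  explicit `ReducibleChainError`, and the sweep treats that as its upper
  stopping point, reporting the last valid α with a warning when ranking
  convergence was not reached first.
- **Payoff comparisons** (symmetry check, response-graph edges) are exact
  for integer-valued payoffs and use relative tolerance 1e-12 otherwise;
  ties within tolerance become weak-tie edges.

## Markov-Conley chains

The response graph places a directed edge between single-deviation
profiles whenever the deviator's payoff does not decrease, annotated
strict vs tie. Sink strongly connected components of this graph (computed
via Tarjan-style SCC and the condensation DAG) are the MCC state spaces;
singleton sinks are pure Nash equilibria. The canonical within-component
chain keeps `self_prob` (default 0.5) at each node and splits the rest so
each strict improvement gets equal mass and each tie gets `tie_ratio`
(default 0.1) times a strict edge's mass — the definition leaves both
unspecified beyond "some probability" and "smaller", so the defaults are
this package's choice and are configurable; component membership, the
ranking-relevant output, does not depend on them. MCCs are invariant under
positive affine payoff transforms, which `affine_transform_check` verifies
directly. At the converged α the stationary support is checked to lie
inside the union of sink components (`mcc_support_check`); this
correspondence is the theoretical anchor of the large-α ranking.

A note on the 2×2 coordination game: viewed through continuous replicator
dynamics its flow has five chain components (four corners plus the interior
mixed fixed point), but the literal sink-SCC computation on the discrete
response graph yields its two strict-equilibrium singletons; the discrete
object is what this package computes.

## Single- vs multi-population mode

For 2-player symmetric games the default mode ranks the strategies of the
shared set on an |S|-state chain where a τ-mutant earns M(τ, σ) against
residents earning M(σ, τ); the general multi-population construction on
profile space remains available via `mode="multi"` and is consistent with
it (both are exercised in the tests). Asymmetric or K > 2 games always use
the multi-population chain and rank full profiles.

## Micro-dynamics

Replicator derivatives and fixed-step RK4 trajectory integration are
provided for one- and two-population games (mirroring the feasibility
limits of simplex analysis); each step renormalizes onto the simplex and a
drift beyond tolerance raises a step-size error. The macro/micro
edge-correspondence check compares, along a simplex edge with all other
populations monomorphic, the macro chain's expected one-step drift
[p_τ p_σ / (m(m−1))]·tanh(αu/2) with the Fermi-modulated replicator drift
x(1−x)·tanh(αu/2): the signs and zero sets agree at every interior point
for all m, and the drifts differ only by the pair-sampling factor
m/(m−1), vanishing as m grows (tested through m ∈ {10, 100, 1000}).

## Synthetic games and what the tests show

Property tests run on seeded uniform-random games (payoffs i.i.d. on
[−1, 1], K ≤ 3, strategy sets of size 2–4 — up to 64 profiles), which is
where the full pipeline including the sweep stays fast enough for hundreds
of instances. These generic games have no payoff ties and modest state
spaces; they exercise irreducibility, row-stochasticity, sparsity bounds,
affine invariance and the support/MCC correspondence, but they do not
emulate structured empirical payoff tables (near-ties from sampled win
rates, strongly transitive ladders, large |S|). Canonical games (RPS,
biased RPS, Battle of the Sexes, matching pennies, coordination) cover
cyclic, asymmetric-coordination and zero-sum structure with exactly known
stationary outcomes. Passing tests therefore establish correctness of the
constructions and solvers, not robustness to noisy empirical payoff
estimation, which is out of scope.

## Known limitations

- Ranking at a fixed α beyond the underflow threshold is refused rather
  than approximated; use the sweep.
- GTH is dense (O(n³)); beyond 2048 states the sparse path is accurate
  only while the chain is far from reducibility, so very large games
  should be ranked at moderate α.
- The general polymorphic fitness form enumerates opponent strategy
  combinations and is exponential in K; it exists for completeness and
  small games, while the ranking pipeline only needs the monomorphic form.
- Empirical meta-game payoff tables (e.g. from large agent tournaments)
  are loaded via the JSON/.nfg readers; none are bundled.
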