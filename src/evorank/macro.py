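"""Discrete-time finite-population selection–mutation dynamics.

Each of the K players is modelled as a finite population of m individuals.
In the small-mutation limit the system lives on monomorphic population
profiles: at most one population ever hosts a mutant, which either fixates
or dies out before the next mutation appears.  Transitions between profiles
are governed by the closed-form fixation probability of a single mutant
under Fermi (logistic) selection with ranking-intensity alpha, and the
profile-level Markov chain's stationary distribution gives the evolutionary
ranking scores.

The chain over |S| = prod_k |S^k| profiles has at most 1 + sum_k(|S^k|-1)
nonzeros per row (self-transition plus single-population switches), so it is
stored sparse and solved with sparse linear algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .games import NormalFormGame, check_symmetric

__all__ = [
    "EvoParams",
    "BirthDeathState",
    "ProfileChain",
    "StationaryDistribution",
    "ReducibleChainError",
    "fitness",
    "fermi_probability",
    "step_probabilities",
    "fixation_probability",
    "fixation_probability_oracle",
    "build_profile_chain",
    "build_single_population_chain",
    "stationary_distribution",
    "sparsity",
    "chain_to_dot",
    "chain_to_tsv",
]

# entries smaller than this are treated as structural zeros in the
# irreducibility check (they are below any meaningful fixation probability)
_ZERO_FLOOR = 1e-300

# switch Eq.-13-style evaluation to log-domain once m*alpha*|u| exceeds this
_LOG_DOMAIN_THRESHOLD = 30.0


class ReducibleChainError(RuntimeError):
    """The profile chain is numerically reducible (alpha too large).

    For finite ranking-intensity the chain is irreducible in exact
    arithmetic; at extreme alpha the fixation probabilities of disfavoured
    mutants underflow and the chain falls apart into closed classes.  The
    remedy is a smaller alpha (or relying on the sweep, which backs off
    automatically).
    """


@dataclass(frozen=True)
class EvoParams:
    """Parameters of the finite-population macro-model.

    m is the number of individuals per population; alpha >= 0 is the
    ranking-intensity (selection strength) of the Fermi rule.  The mutation
    rate is the analytic limit mu -> 0 and deliberately has no field here.
    """

    m: int = 50
    alpha: float = 0.1
    stationary_tol: float = 1e-10
    neutral_fitness_tol: float = 1e-12

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("population size m must be at least 2")
        if self.alpha < 0:
            raise ValueError("ranking-intensity alpha must be non-negative")
        if self.stationary_tol <= 0 or self.neutral_fitness_tol <= 0:
            raise ValueError("tolerances must be positive")

    def with_alpha(self, alpha: float) -> "EvoParams":
        return EvoParams(self.m, alpha, self.stationary_tol,
                         self.neutral_fitness_tol)


@dataclass(frozen=True)
class BirthDeathState:
    """Mutant/resident counts in the focal population (p_tau + p_sigma = m)."""

    p_tau: int
    p_sigma: int

    def __post_init__(self):
        if self.p_tau < 0 or self.p_sigma < 0:
            raise ValueError("counts must be non-negative")


def fitness(game: NormalFormGame, k: int, s_k: int,
            opponents: Sequence[int]) -> float:
    """Fitness of an individual playing s_k in population k.

    With all other populations monomorphic at `opponents` (the K-1 strategy
    indices of the other players, in player order) the fitness is simply the
    payoff entry M^k(s_k, s_{-k}).
    """
    opponents = tuple(int(i) for i in opponents)
    if len(opponents) != game.num_players - 1:
        raise ValueError("opponents must list one strategy per other player")
    profile = opponents[:k] + (int(s_k),) + opponents[k:]
    return game.payoff(k, profile)


def fitness_polymorphic(game: NormalFormGame, k: int, s_k: int,
                        opponent_counts: Sequence[Sequence[int]],
                        m: int) -> float:
    """General fitness under uniformly sampled polymorphic opponents.

    `opponent_counts[c]` gives, for each other population c (in player order,
    skipping k), the count of individuals per strategy; counts must sum to m.
    Reduces to :func:`fitness` when every opponent population is monomorphic.
    """
    others = [c for c in range(game.num_players) if c != k]
    if len(opponent_counts) != len(others):
        raise ValueError("one count vector per opponent population required")
    fracs = []
    for c, counts in zip(others, opponent_counts):
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (game.shape[c],) or counts.sum() != m:
            raise ValueError(
                f"counts for population {c + 1} must sum to m={m} over "
                f"{game.shape[c]} strategies"
            )
        fracs.append(counts / m)
    total = 0.0
    M = game.payoffs[k]
    import itertools
    for combo in itertools.product(*(range(game.shape[c]) for c in others)):
        w = 1.0
        for frac, i in zip(fracs, combo):
            w *= frac[i]
        if w == 0.0:
            continue
        profile = list(combo)
        profile.insert(k, int(s_k))
        total += w * float(M[tuple(profile)])
    return total


def fermi_probability(alpha: float, f_sigma: float, f_tau: float) -> float:
    """Probability that the tau-individual copies the sigma-individual.

    Logistic (Fermi) selection: (1 + exp(alpha*(f_tau - f_sigma)))^-1.
    Overflow-safe for arbitrarily large |alpha*(f_tau - f_sigma)|.
    """
    x = alpha * (f_tau - f_sigma)
    if x > 0:
        # 1/(1+e^x) = e^-x/(1+e^-x)
        ex = math.exp(-x)
        return ex / (1.0 + ex)
    return 1.0 / (1.0 + math.exp(x))


def step_probabilities(state: BirthDeathState, params: EvoParams,
                       f_tau: float, f_sigma: float) -> tuple:
    """One-step (decrease, increase) probabilities of the mutant count.

    T^(-/+1) = [p_tau p_sigma / (m(m-1))] * (1 + e^{+/- alpha (f_tau-f_sigma)})^-1.
    Both vanish at the absorbing boundaries p_tau in {0, m}.
    """
    m = params.m
    p_tau, p_sigma = state.p_tau, state.p_sigma
    if p_tau + p_sigma != m:
        raise ValueError("p_tau + p_sigma must equal m")
    pair = p_tau * p_sigma / (m * (m - 1))
    if pair == 0.0:
        return 0.0, 0.0
    # decrease: the tau-individual copies sigma, (1+e^{+alpha u})^{-1}
    dec = pair * fermi_probability(params.alpha, f_sigma, f_tau)
    # increase: the sigma-individual copies tau, (1+e^{-alpha u})^{-1}
    inc = pair * fermi_probability(params.alpha, f_tau, f_sigma)
    return dec, inc


def _fixation_from_u(m: int, alpha: float, u: float, neutral_tol: float) -> float:
    """Closed-form fixation probability from fitness difference u = f_tau - f_sigma."""
    scale = max(1.0, abs(u))
    if alpha == 0.0 or abs(u) <= neutral_tol * scale:
        return 1.0 / m
    a = alpha * u
    if abs(m * a) <= _LOG_DOMAIN_THRESHOLD:
        # (1 - e^-a)/(1 - e^-ma) = expm1(-a)/expm1(-ma)
        return math.expm1(-a) / math.expm1(-m * a)
    if a > 0:
        # e^{-ma} underflow-safe: denominator -> 1
        return -math.expm1(-a) / -math.expm1(-m * a)
    # a < 0 with large |ma|: evaluate (e^{|a|}-1)/(e^{m|a|}-1) in log-domain
    b = -a
    log_num = b + _log1mexp(b)
    log_den = m * b + _log1mexp(m * b)
    log_rho = log_num - log_den
    if log_rho < -745.0:
        return 0.0
    return math.exp(log_rho)


def _log1mexp(x: float) -> float:
    """log(1 - e^{-x}) for x > 0, numerically stable."""
    if x > 0.6931471805599453:  # ln 2
        return math.log1p(-math.exp(-x))
    return math.log(-math.expm1(-x))


def fixation_probability(params: EvoParams, f_tau: float, f_sigma: float) -> float:
    """Probability that a single tau-mutant fixates in a sigma-resident population.

    Closed form of the birth–death absorption probability under Fermi
    selection: rho = (1 - e^{-alpha u}) / (1 - e^{-m alpha u}) with
    u = f_tau - f_sigma, and rho = 1/m when the fitnesses are equal (to
    within ``neutral_fitness_tol``, relative).  Evaluated via expm1 for
    moderate exponents and in log-domain when m*alpha*|u| is large, so the
    result is accurate and in [0, 1] for arbitrarily strong selection.
    """
    u = f_tau - f_sigma
    scale = max(1.0, abs(f_tau), abs(f_sigma))
    if abs(u) <= params.neutral_fitness_tol * scale:
        return 1.0 / params.m
    rho = _fixation_from_u(params.m, params.alpha, u, 0.0)
    return min(1.0, max(0.0, rho))


def fixation_probability_oracle(params: EvoParams, f_tau: float,
                                f_sigma: float) -> float:
    """Brute-force fixation probability by solving the birth–death chain.

    Builds the (m-1)-state interior linear system for the probability of
    absorption at p_tau = m, using only :func:`step_probabilities` — no use
    of the closed form.  Intended for modest m (<= a few hundred).
    """
    m = params.m
    n = m - 1
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(1, m):
        dec, inc = step_probabilities(
            BirthDeathState(i, m - i), params, f_tau, f_sigma)
        row = i - 1
        # x_i = dec*x_{i-1} + inc*x_{i+1} + (1-dec-inc)*x_i
        A[row, row] = dec + inc
        if i - 1 >= 1:
            A[row, row - 1] = -dec
        if i + 1 <= m - 1:
            A[row, row + 1] = -inc
        else:
            b[row] = inc  # x_m = 1
    x = np.linalg.solve(A, b)
    return float(x[0])


# ---------------------------------------------------------------------------
# profile chain


@dataclass(frozen=True)
class ProfileChain:
    """Sparse row-stochastic Markov chain over pure strategy profiles."""

    states: tuple              # ordered profiles (row-major) or strategy ids
    labels: tuple              # display label per state
    matrix: sp.csr_matrix = field(compare=False)
    eta: float = 0.0
    params: EvoParams = None
    single_population: bool = False

    @property
    def num_states(self) -> int:
        return len(self.states)


def _transition_eta(game: NormalFormGame) -> float:
    denom = sum(n - 1 for n in game.shape)
    if denom == 0:
        raise ValueError(
            "every strategy set is a singleton: no mutations are possible "
            "and the transition normalizer eta is undefined"
        )
    return 1.0 / denom


def build_profile_chain(game: NormalFormGame, params: EvoParams) -> ProfileChain:
    """Multi-population Markov chain over all pure strategy profiles.

    C[i, j] = eta * rho for profile pairs differing in exactly one player's
    strategy (rho the fixation probability of the deviating strategy in that
    player's population), diagonal entries absorb the rest, all other entries
    zero.  eta = 1 / sum_k (|S^k| - 1).
    """
    eta = _transition_eta(game)
    shape = game.shape
    states = list(game.profiles())
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    rows, cols, vals = [], [], []
    diag = np.ones(n)
    for i, s in enumerate(states):
        for k in range(game.num_players):
            s_k = s[k]
            f_sigma = game.payoffs[k][s]
            for tau in range(shape[k]):
                if tau == s_k:
                    continue
                t = s[:k] + (tau,) + s[k + 1:]
                f_tau = game.payoffs[k][t]
                rho = fixation_probability(params, float(f_tau), float(f_sigma))
                p = eta * rho
                if p > 0.0:
                    rows.append(i)
                    cols.append(index[t])
                    vals.append(p)
                diag[i] -= p
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(np.clip(diag, 0.0, 1.0))
    C = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    labels = tuple(game.profile_label(s) for s in states)
    return ProfileChain(tuple(states), labels, C, eta, params, False)


def build_single_population_chain(game: NormalFormGame,
                                  params: EvoParams) -> ProfileChain:
    """Single-population chain for a 2-player symmetric game.

    States are the strategies of the shared set.  A tau-mutant in a
    sigma-resident population has fitness M(tau, sigma) while residents earn
    M(sigma, tau); transitions use eta = 1/(|S|-1) and the closed-form
    fixation probability.
    """
    if game.num_players != 2 or not check_symmetric(game):
        raise ValueError("single-population reduction requires a 2-player "
                         "symmetric game")
    M = game.payoffs[0]
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least two strategies")
    eta = 1.0 / (n - 1)
    rows, cols, vals = [], [], []
    diag = np.ones(n)
    for sigma in range(n):
        for tau in range(n):
            if tau == sigma:
                continue
            rho = fixation_probability(
                params, float(M[tau, sigma]), float(M[sigma, tau]))
            p = eta * rho
            if p > 0.0:
                rows.append(sigma)
                cols.append(tau)
                vals.append(p)
            diag[sigma] -= p
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(np.clip(diag, 0.0, 1.0))
    C = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    states = tuple((i,) for i in range(n))
    labels = tuple(game.strategy_labels[0])
    return ProfileChain(states, labels, C, eta, params, True)


@dataclass(frozen=True)
class StationaryDistribution:
    """Unique left fixed point pi of an irreducible row-stochastic chain."""

    mass: np.ndarray
    residual: float

    def __iter__(self):
        return iter(self.mass)

    def __len__(self):
        return len(self.mass)


def _assert_irreducible(C: sp.csr_matrix) -> None:
    P = C.copy()
    P.data = np.where(np.abs(P.data) > _ZERO_FLOOR, 1.0, 0.0)
    P.eliminate_zeros()
    ncomp, _ = csgraph.connected_components(P, directed=True, connection="strong")
    if ncomp != 1:
        raise ReducibleChainError(
            f"profile chain is numerically reducible ({ncomp} strongly "
            "connected classes); reduce the ranking-intensity alpha"
        )


# chains up to this many states are solved by dense state elimination (GTH)
_GTH_MAX_STATES = 2048


def _gth_stationary(C: sp.csr_matrix) -> np.ndarray:
    """Stationary distribution by Grassmann–Taksar–Heyman state elimination.

    Subtraction-free, so each mass is computed to high entrywise relative
    accuracy even when the chain is nearly reducible (strong selection
    leaves only minuscule leak probabilities between sink profiles, where a
    generic linear solve silently collapses onto one of them).  The
    diagonal of C is never referenced, so its cancellation error is
    irrelevant.  O(n^3), dense.
    """
    P = np.asarray(C.todense(), dtype=float).copy()
    n = P.shape[0]
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n - 1, 0, -1):
            scale = P[k, :k].sum()
            if scale <= 0.0:
                raise ReducibleChainError(
                    "state elimination hit a state with no outflow; the "
                    "chain is numerically reducible — reduce alpha"
                )
            P[k, :k] /= scale
            P[:k, :k] += np.outer(P[:k, k], P[k, :k])
            P[:k, k] /= scale
        pi = np.zeros(n)
        pi[0] = 1.0
        for k in range(1, n):
            pi[k] = pi[:k] @ P[:k, k]
            top = pi[:k + 1].max()
            if top > 1e250:  # keep unnormalized masses representable
                pi[:k + 1] /= top
        total = pi.sum()
    if not (np.all(np.isfinite(pi)) and np.isfinite(total) and total > 0):
        raise ReducibleChainError(
            "stationary masses overflowed during state elimination; the "
            "chain is effectively reducible — reduce alpha"
        )
    return pi / total


def stationary_distribution(chain: ProfileChain) -> StationaryDistribution:
    """Solve pi^T C = pi^T, sum(pi) = 1 on the chain.

    Verifies irreducibility of the positive-entry graph first (guaranteed in
    exact arithmetic for finite alpha, but checked because extreme alpha can
    underflow transition entries).  Chains with up to a couple of thousand
    states are solved by GTH state elimination, which stays entrywise
    accurate even when strong selection makes the chain nearly reducible.
    Larger chains use the sparse linear system (C^T - I) pi = 0 with the
    normalization constraint substituted for one equation, with a
    power-iteration fallback; an unsatisfied residual raises rather than
    returning a silent wrong answer.
    """
    C = chain.matrix
    n = C.shape[0]
    _assert_irreducible(C)
    tol = chain.params.stationary_tol if chain.params is not None else 1e-10

    def _residual(v):
        return float(np.max(np.abs(v @ C - v)))

    if n <= _GTH_MAX_STATES:
        pi = _gth_stationary(C)
        return StationaryDistribution(pi, _residual(pi))

    A = (C.T - sp.identity(n, format="csr")).tolil()
    A[n - 1, :] = 1.0  # replace last equation with sum(pi) = 1
    b = np.zeros(n)
    b[n - 1] = 1.0
    pi = None
    try:
        pi = spla.spsolve(A.tocsr(), b)
    except Exception:
        pi = None
    if pi is not None and np.all(np.isfinite(pi)):
        pi = np.clip(pi, 0.0, None)
        total = pi.sum()
        if total > 0:
            pi = pi / total
        else:
            pi = None
    else:
        pi = None

    if pi is None or _residual(pi) > tol:
        # damped power iteration on the irreducible chain
        pi = np.full(n, 1.0 / n)
        for _ in range(200_000):
            new = pi @ C
            new = np.clip(new, 0.0, None)
            new /= new.sum()
            if np.max(np.abs(new - pi)) < tol / 10:
                pi = new
                break
            pi = new
    res = _residual(pi)
    if res > tol:
        raise ReducibleChainError(
            f"stationary solve did not reach residual tolerance ({res:.2e} > "
            f"{tol:.2e}); the chain may be numerically reducible — reduce alpha"
        )
    return StationaryDistribution(pi, res)


def sparsity(game: NormalFormGame) -> float:
    """Closed-form sparsity of the profile transition matrix C.

    1 - |S| (1 + sum_k (|S^k| - 1)) / |S|^2, where |S| is the number of pure
    profiles: each row holds only the self-transition plus the
    single-population switches.
    """
    _transition_eta(game)  # validates eta is well-defined
    S = game.num_profiles
    per_row = 1 + sum(n - 1 for n in game.shape)
    return 1.0 - S * per_row / S**2


# ---------------------------------------------------------------------------
# exports


def chain_to_dot(chain: ProfileChain, dist: StationaryDistribution | None = None,
                 min_multiple: float = 1.0) -> str:
    """DOT digraph of the chain; edges labelled as multiples of the neutral
    fixation baseline rho_m = 1/m, edges below ``min_multiple`` times the
    baseline suppressed (the usual readability convention)."""
    m = chain.params.m if chain.params is not None else 50
    rho_m = 1.0 / m
    lines = ["digraph chain {"]
    for i, lab in enumerate(chain.labels):
        extra = f"\\npi={dist.mass[i]:.3g}" if dist is not None else ""
        lines.append(f'  n{i} [label="{lab}{extra}"];')
    coo = chain.matrix.tocoo()
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if i == j:
            continue
        mult = (v / chain.eta) / rho_m
        if mult < min_multiple:
            continue
        lines.append(f'  n{i} -> n{j} [label="{mult:.3g}"];')
    lines.append("}")
    return "\n".join(lines)


def chain_to_tsv(chain: ProfileChain) -> str:
    """TSV edge list: source label, target label, transition probability."""
    out = ["source\ttarget\tprobability"]
    coo = chain.matrix.tocoo()
    for i, j, v in zip(coo.row, coo.col, coo.data):
        out.append(f"{chain.labels[i]}\t{chain.labels[j]}\t{v!r}")
    return "\n".join(out) + "\n"
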