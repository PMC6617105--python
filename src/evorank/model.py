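"""The alpha-Rank procedure: ranking-intensity sweep, rankings, diagnostics.

The method proceeds in four steps: (1) assemble the meta-game payoff
tensors, (2) build the profile-level transition matrix at a given
ranking-intensity alpha, (3) solve for its unique stationary distribution,
and (4) read the ranking off the ordered stationary masses.  Because the
strong-selection (large-alpha) limit — where the distribution concentrates
on the Markov-Conley chains — is not directly computable, alpha is swept
upward exponentially until the induced ranking stops changing.

The public surface follows the model/results idiom: :class:`AlphaRank` is
built from a game, its :meth:`AlphaRank.fit` runs the sweep and returns an
:class:`AlphaRankResults` carrying the scores, the sweep trace, the chain,
the MCC cross-check, and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mcc as _mcc
from .games import NormalFormGame, check_symmetric
from .macro import (EvoParams, ProfileChain, ReducibleChainError,
                    StationaryDistribution, build_profile_chain,
                    build_single_population_chain, stationary_distribution)

__all__ = [
    "SweepConfig",
    "SweepResult",
    "Ranking",
    "AlphaRank",
    "AlphaRankResults",
    "alpha_sweep",
    "rank_from_distribution",
    "alpharank",
    "mcc_support_check",
]


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of the exponential ranking-intensity sweep.

    The sweep evaluates alpha0 * factor**t and declares convergence once the
    induced ranking order is identical over ``window`` consecutive values
    and the largest change in any stationary mass is below ``mass_tol``.
    """

    alpha0: float = 0.01
    factor: float = 2.0
    max_steps: int = 40
    window: int = 3
    mass_tol: float = 1e-4
    tie_tol: float = 1e-6

    def __post_init__(self):
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.factor <= 1:
            raise ValueError("factor must exceed 1")
        if self.max_steps < 1 or self.window < 1:
            raise ValueError("max_steps and window must be positive")


@dataclass(frozen=True)
class SweepResult:
    """Stationary distributions along an increasing alpha grid."""

    alphas: tuple
    distributions: tuple
    converged: bool
    converged_alpha: float | None
    halted_reducible: bool = False

    @property
    def final(self) -> StationaryDistribution:
        return self.distributions[-1]

    @property
    def final_alpha(self) -> float:
        return self.alphas[-1]

    def to_frame(self, labels) -> pd.DataFrame:
        """Sweep trace as a DataFrame (one row per alpha, one column per state)."""
        data = np.vstack([d.mass for d in self.distributions])
        return pd.DataFrame(data, index=list(self.alphas), columns=list(labels))


@dataclass(frozen=True)
class Ranking:
    """Ordered stationary masses with tie grouping.

    ``entries`` is a list of (label, score, rank) with nonincreasing score;
    states whose scores differ by less than the tie tolerance share a rank
    ordinal, and the secondary order is the original state enumeration.
    """

    entries: tuple
    tie_tol: float

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @property
    def labels(self):
        return tuple(e[0] for e in self.entries)

    @property
    def scores(self):
        return tuple(e[1] for e in self.entries)

    def top(self):
        """Entries sharing the best rank ordinal."""
        best = self.entries[0][2]
        return tuple(e for e in self.entries if e[2] == best)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, lab, sc) for lab, sc, r in self.entries],
            columns=["rank", "agent", "score"],
        )


def rank_from_distribution(dist: StationaryDistribution, labels,
                           tie_tol: float = 1e-6) -> Ranking:
    """Ranking from stationary masses; near-equal scores share an ordinal."""
    labels = list(labels)
    mass = np.asarray(dist.mass, dtype=float)
    order = sorted(range(len(mass)), key=lambda i: (-mass[i], i))
    entries = []
    rank = 0
    group_ref = None  # score that opened the current tie group
    for pos, i in enumerate(order):
        score = float(mass[i])
        if group_ref is None or group_ref - score >= tie_tol:
            rank = pos + 1
            group_ref = score
        entries.append((labels[i], score, rank))
    return Ranking(tuple(entries), tie_tol)


def _order_signature(mass: np.ndarray, tie_tol: float) -> tuple:
    """Tie-aware ranking signature used for sweep convergence."""
    order = sorted(range(len(mass)), key=lambda i: (-mass[i], i))
    sig = []
    rank = 0
    prev = None
    for pos, i in enumerate(order):
        if prev is None or prev - mass[i] >= tie_tol:
            rank = pos + 1
            prev = mass[i]
        sig.append((i, rank))
    return tuple(sig)


def _build_chain(game: NormalFormGame, params: EvoParams,
                 single_population: bool) -> ProfileChain:
    if single_population:
        return build_single_population_chain(game, params)
    return build_profile_chain(game, params)


def alpha_sweep(game: NormalFormGame, params: EvoParams,
                alpha0: float = 0.01, factor: float = 2.0,
                max_steps: int = 40, window: int = 3,
                mass_tol: float = 1e-4, tie_tol: float = 1e-6,
                single_population: bool = False) -> SweepResult:
    """Exponential sweep over the ranking-intensity alpha.

    Evaluates stationary distributions at alpha0 * factor**t, stopping when
    the induced ranking order is identical over ``window`` consecutive
    values with all masses stable to ``mass_tol``, or when the chain first
    becomes numerically reducible (the last valid alpha is then reported
    with ``halted_reducible=True``).  Fully deterministic.
    """
    cfg = SweepConfig(alpha0, factor, max_steps, window, mass_tol, tie_tol)
    alphas, dists = [], []
    signatures = []
    converged = False
    converged_alpha = None
    halted = False
    for t in range(cfg.max_steps):
        alpha = cfg.alpha0 * cfg.factor ** t
        try:
            chain = _build_chain(game, params.with_alpha(alpha), single_population)
            dist = stationary_distribution(chain)
        except ReducibleChainError:
            halted = True
            break
        alphas.append(alpha)
        dists.append(dist)
        signatures.append(_order_signature(dist.mass, cfg.tie_tol))
        if len(dists) >= cfg.window:
            recent = signatures[-cfg.window:]
            stable_order = all(s == recent[0] for s in recent)
            stable_mass = max(
                float(np.max(np.abs(dists[-j - 1].mass - dists[-j - 2].mass)))
                for j in range(cfg.window - 1)
            ) < cfg.mass_tol
            if stable_order and stable_mass:
                converged = True
                converged_alpha = alpha
                break
    if not alphas:
        raise ReducibleChainError(
            "chain numerically reducible already at the initial alpha; "
            "decrease alpha0"
        )
    return SweepResult(tuple(alphas), tuple(dists), converged,
                       converged_alpha, halted)


def mcc_support_check(game: NormalFormGame, chain: ProfileChain,
                      dist: StationaryDistribution,
                      mass_tol: float = 1e-3) -> dict:
    """Cross-check the large-alpha stationary support against the MCCs.

    In the strong-selection limit the chain coincides with the
    Markov-Conley chains, so every state carrying more than ``mass_tol``
    stationary mass must lie inside a sink strongly connected component of
    the response graph.  Returns a report with the support, the per-component
    aggregated mass, and a boolean verdict.
    """
    if chain.single_population:
        graph = _mcc.build_single_population_response_graph(game)
    else:
        graph = _mcc.build_response_graph(game)
    mccs = _mcc.sink_components(graph)
    state_index = {s: i for i, s in enumerate(chain.states)}
    support = {s for s, p in zip(chain.states, dist.mass) if p > mass_tol}
    union = mccs.union
    comp_mass = []
    for comp in mccs.components:
        total = sum(float(dist.mass[state_index[s]]) for s in comp
                    if s in state_index)
        comp_mass.append(total)
    return {
        "contained": support <= union,
        "support": sorted(support),
        "num_components": len(mccs),
        "component_mass": comp_mass,
        "pure_nash": list(mccs.is_pure_nash),
        "mass_in_components": float(sum(comp_mass)),
        "mass_tol": mass_tol,
    }


# ---------------------------------------------------------------------------
# model / results


class AlphaRank:
    """Evolutionary ranking model for a K-player normal-form (meta-)game.

    Parameters
    ----------
    game : NormalFormGame
        The game (or empirical meta-game) whose strategies/agents to rank.
    m : int
        Population size of each finite population (default 50).
    mode : {"auto", "single", "multi"}
        "single" uses the single-population reduction (2-player symmetric
        games only; ranks strategies), "multi" the full multi-population
        chain (ranks strategy profiles).  "auto" picks "single" exactly when
        the game is 2-player symmetric.

    Examples
    --------
    >>> from evorank import make_canonical_game, AlphaRank
    >>> res = AlphaRank(make_canonical_game("rps")).fit()
    >>> [round(s, 3) for s in res.ranking.scores]
    [0.333, 0.333, 0.333]
    """

    def __init__(self, game: NormalFormGame, m: int = 50, mode: str = "auto",
                 stationary_tol: float = 1e-10):
        if mode not in ("auto", "single", "multi"):
            raise ValueError("mode must be 'auto', 'single' or 'multi'")
        if mode == "auto":
            mode = ("single" if game.num_players == 2 and check_symmetric(game)
                    else "multi")
        if mode == "single" and (game.num_players != 2
                                 or not check_symmetric(game)):
            raise ValueError("single-population mode requires a 2-player "
                             "symmetric game")
        if sum(n - 1 for n in game.shape) == 0:
            raise ValueError("game has a single profile; nothing to rank")
        self.game = game
        self.mode = mode
        self.params = EvoParams(m=m, alpha=0.0, stationary_tol=stationary_tol)

    @classmethod
    def from_payoffs(cls, payoffs, labels=None, **kwargs) -> "AlphaRank":
        """Build from raw per-player payoff tensors (lists or arrays)."""
        tensors = [np.asarray(M, dtype=float) for M in payoffs]
        K = len(tensors)
        shape = tensors[0].shape
        if labels is None:
            labels = [[f"s{k + 1}_{i}" for i in range(shape[k])]
                      for k in range(K)]
        game = NormalFormGame(K, labels, tensors)
        return cls(game, **kwargs)

    def fit(self, alpha0: float = 0.01, factor: float = 2.0,
            max_steps: int = 40, window: int = 3, mass_tol: float = 1e-4,
            tie_tol: float = 1e-6) -> "AlphaRankResults":
        """Run the sweep and return the fitted results."""
        single = self.mode == "single"
        sweep = alpha_sweep(self.game, self.params, alpha0, factor, max_steps,
                            window, mass_tol, tie_tol, single_population=single)
        final_alpha = sweep.final_alpha
        chain = _build_chain(self.game, self.params.with_alpha(final_alpha),
                             single)
        dist = sweep.final
        ranking = rank_from_distribution(dist, chain.labels, tie_tol)
        mcc_report = mcc_support_check(self.game, chain, dist)
        config = {
            "m": self.params.m, "mode": self.mode, "alpha0": alpha0,
            "factor": factor, "max_steps": max_steps, "window": window,
            "mass_tol": mass_tol, "tie_tol": tie_tol,
        }
        return AlphaRankResults(self, chain, dist, sweep, ranking,
                                mcc_report, config)

    def fit_at(self, alpha: float) -> "AlphaRankResults":
        """Rank at one fixed ranking-intensity (no sweep)."""
        single = self.mode == "single"
        chain = _build_chain(self.game, self.params.with_alpha(alpha), single)
        dist = stationary_distribution(chain)
        sweep = SweepResult((alpha,), (dist,), False, None)
        ranking = rank_from_distribution(dist, chain.labels)
        mcc_report = mcc_support_check(self.game, chain, dist)
        config = {"m": self.params.m, "mode": self.mode, "alpha": alpha}
        return AlphaRankResults(self, chain, dist, sweep, ranking,
                                mcc_report, config)


@dataclass(frozen=True)
class AlphaRankResults:
    """Fitted alpha-Rank: scores, sweep trace, chain, and diagnostics."""

    model: AlphaRank = field(repr=False)
    chain: ProfileChain = field(repr=False)
    distribution: StationaryDistribution
    sweep: SweepResult = field(repr=False)
    ranking: Ranking
    mcc_report: dict = field(repr=False)
    config: dict = field(repr=False)

    @property
    def scores(self) -> pd.Series:
        return pd.Series(dict(zip(self.chain.labels, self.distribution.mass)),
                         name="score")

    @property
    def converged(self) -> bool:
        return self.sweep.converged

    @property
    def alpha(self) -> float:
        return self.sweep.final_alpha

    def sweep_frame(self) -> pd.DataFrame:
        return self.sweep.to_frame(self.chain.labels)

    def summary(self) -> str:
        """Human-readable fit summary (ranking table plus diagnostics)."""
        lines = [
            "alpha-Rank results",
            "==================",
            f"game: {self.model.game.name or '<unnamed>'}   "
            f"mode: {self.model.mode}   m: {self.model.params.m}",
            f"alpha: {self.alpha:g}   converged: {self.converged}   "
            f"sweep steps: {len(self.sweep.alphas)}",
            f"stationary residual: {self.distribution.residual:.2e}",
            f"MCC support contained: {self.mcc_report['contained']}   "
            f"components: {self.mcc_report['num_components']}",
            "",
            self.ranking.to_frame().to_string(index=False),
        ]
        if self.sweep.halted_reducible:
            lines.insert(5, "warning: sweep halted by numerical reducibility "
                            "before ranking convergence")
        return "\n".join(lines)

    def manifest(self) -> str:
        """JSON run manifest: configuration and convergence facts."""
        doc = dict(self.config)
        doc.update(
            final_alpha=self.alpha,
            converged=self.converged,
            halted_reducible=self.sweep.halted_reducible,
            residual=self.distribution.residual,
            num_states=self.chain.num_states,
        )
        return json.dumps(doc, indent=1)


def alpharank(game: NormalFormGame, m: int = 50, mode: str = "auto",
              **sweep_kwargs):
    """Functional four-step alpha-Rank; returns (ranking, sweep, chain)."""
    res = AlphaRank(game, m=m, mode=mode).fit(**sweep_kwargs)
    return res.ranking, res.sweep, res.chain
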