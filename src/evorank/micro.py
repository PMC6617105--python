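"""Continuous-time replicator micro-dynamics for one- and two-player games.

The replicator equations track the proportions of strategies in infinite
populations: for a single population with payoff matrix A,
x_i' = x_i((Ax)_i - x^T A x); for two asymmetric populations (A, B),
x_i' = x_i((Ay)_i - x^T A y) and y_j' = y_j((x^T B)_j - x^T B y).  These
micro-dynamics are only feasible for small numbers of players, which is why
the finite-population macro-model carries the general-K ranking; here they
serve for trajectory plots and for the edge-correspondence check between
the two models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .games import NormalFormGame
from .macro import BirthDeathState, EvoParams, step_probabilities

__all__ = [
    "ReplicatorState",
    "replicator_derivative",
    "integrate_trajectory",
    "edge_correspondence_check",
    "trajectory_to_tsv",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class ReplicatorState:
    """Per-population mixed strategies (each a probability vector)."""

    mixtures: tuple

    def __post_init__(self):
        mixes = tuple(np.asarray(x, dtype=float) for x in self.mixtures)
        object.__setattr__(self, "mixtures", mixes)
        for x in mixes:
            if np.any(x < -_SIMPLEX_TOL) or abs(x.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError("each mixture must be a probability vector")


def _check_small(game: NormalFormGame) -> None:
    if game.num_players > 2:
        raise ValueError(
            "replicator micro-dynamics are implemented for at most two "
            "populations; use the finite-population macro-model for K > 2"
        )


def replicator_derivative(game: NormalFormGame,
                          state: ReplicatorState) -> tuple:
    """Time-derivatives of the replicator dynamics at ``state``.

    Single population: x_i' = x_i((Ax)_i - x^T A x) with A the (first
    player's) payoff matrix.  Two populations: the asymmetric bimatrix form
    with A for player 1 against y and B for player 2 against x.
    """
    _check_small(game)
    if game.num_players == 1:
        (x,) = state.mixtures
        a = game.payoffs[0]
        mean = float(x @ a)
        return (x * (a - mean),)
    if len(state.mixtures) == 1:
        # single-population restriction of a symmetric 2-player game
        (x,) = state.mixtures
        A = game.payoffs[0]
        Ax = A @ x
        return (x * (Ax - x @ Ax),)
    A, B = game.payoffs
    x, y = state.mixtures
    Ay = A @ y
    xB = x @ B
    return (x * (Ay - x @ Ay), y * (xB - xB @ y))


def integrate_trajectory(game: NormalFormGame, start: ReplicatorState,
                         horizon: float, step: float) -> list:
    """Fixed-step 4th-order Runge-Kutta integration of the replicator flow.

    Returns a list of (time, ReplicatorState); every state is renormalized
    onto the simplex (tolerance 1e-9) and a state drifting further off the
    simplex raises a step-size error.  Deterministic.
    """
    _check_small(game)
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(round(horizon / step))
    mixes = [x.copy() for x in start.mixtures]
    traj = [(0.0, ReplicatorState(tuple(m.copy() for m in mixes)))]

    def deriv(vectors):
        return replicator_derivative(
            game, ReplicatorState(tuple(vectors)))

    for i in range(1, n_steps + 1):
        k1 = deriv(mixes)
        k2 = deriv([m + 0.5 * step * d for m, d in zip(mixes, k1)])
        k3 = deriv([m + 0.5 * step * d for m, d in zip(mixes, k2)])
        k4 = deriv([m + step * d for m, d in zip(mixes, k3)])
        new = []
        for m, d1, d2, d3, d4 in zip(mixes, k1, k2, k3, k4):
            v = m + (step / 6.0) * (d1 + 2 * d2 + 2 * d3 + d4)
            drift = abs(v.sum() - 1.0)
            if drift > 1e-6 or np.any(v < -1e-6):
                raise RuntimeError(
                    f"state left the simplex (drift {drift:.2e}); "
                    "reduce the integration step"
                )
            v = np.clip(v, 0.0, None)
            v /= v.sum()
            new.append(v)
        mixes = new
        traj.append((i * step, ReplicatorState(tuple(m.copy() for m in mixes))))
    return traj


def edge_correspondence_check(game: NormalFormGame, player: int,
                              strategies: tuple, opponents: tuple,
                              params: EvoParams,
                              fractions: np.ndarray | None = None) -> dict:
    """Compare macro drift and Fermi-replicator drift along a simplex edge.

    On the edge where population ``player`` mixes strategies
    ``(tau, sigma) = strategies`` and every other population is monomorphic
    at ``opponents``, the macro-model's expected one-step drift is
    T^(+1) - T^(-1) = [p_tau p_sigma / (m(m-1))] tanh(alpha u / 2) with
    u = f_tau - f_sigma; the continuous Fermi-modulated replicator drift on
    the same edge is x(1-x) tanh(alpha u / 2).  The two agree in sign and
    zero set at every interior point, and the scaled macro drift converges
    to the continuous one as m grows.  Returns the grid, both drifts and
    per-point sign agreement.
    """
    tau, sigma = strategies
    opp = tuple(int(i) for i in opponents)
    prof_sigma = opp[:player] + (int(sigma),) + opp[player:]
    prof_tau = opp[:player] + (int(tau),) + opp[player:]
    f_tau = game.payoff(player, prof_tau)
    f_sigma = game.payoff(player, prof_sigma)
    u = f_tau - f_sigma
    m = params.m
    if fractions is None:
        counts = np.arange(1, m)
    else:
        counts = np.unique(np.clip(np.round(np.asarray(fractions) * m), 1,
                                   m - 1).astype(int))
    grid, macro, cont, agree = [], [], [], []
    for p_tau in counts:
        x = p_tau / m
        dec, inc = step_probabilities(
            BirthDeathState(int(p_tau), m - int(p_tau)), params, f_tau, f_sigma)
        d_macro = inc - dec
        d_cont = x * (1 - x) * np.tanh(params.alpha * u / 2.0)
        grid.append(x)
        macro.append(d_macro)
        cont.append(d_cont)
        agree.append(np.sign(d_macro) == np.sign(d_cont))
    return {
        "fractions": np.asarray(grid),
        "macro_drift": np.asarray(macro),
        "continuous_drift": np.asarray(cont),
        "sign_agree": np.asarray(agree, dtype=bool),
        "all_agree": bool(all(agree)),
        "fitness_difference": u,
    }


def trajectory_to_tsv(trajectory) -> str:
    """TSV export: time column plus one column per mixture coordinate."""
    _, first = trajectory[0]
    header = ["time"]
    for k, x in enumerate(first.mixtures):
        header += [f"p{k + 1}_s{i}" for i in range(len(x))]
    rows = ["\t".join(header)]
    for t, state in trajectory:
        vals = [repr(float(t))]
        for x in state.mixtures:
            vals += [repr(float(v)) for v in x]
        rows.append("\t".join(vals))
    return "\n".join(rows) + "\n"
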