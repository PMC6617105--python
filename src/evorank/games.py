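"""K-player normal-form games: data model, canonical games, random games, file I/O.

A normal-form game here is the meta-game abstraction used in empirical
game-theoretic analysis: each "strategy" may be a whole agent, and the payoff
tensors hold empirical win rates or returns.  The game is stored fully
expanded — one K-dimensional payoff tensor per player — even when symmetric,
so that all downstream chain constructions share one code path.
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NormalFormGame",
    "Profile",
    "make_canonical_game",
    "random_game",
    "payoff_of_profile",
    "check_symmetric",
    "read_game",
    "write_game",
    "count_two_faces",
    "CANONICAL_GAMES",
]

#: relative tolerance for payoff equality on non-integer payoffs
PAYOFF_RTOL = 1e-12


Profile = tuple  # length-K tuple of 0-based strategy indices


@dataclass(frozen=True)
class NormalFormGame:
    """A K-player normal-form (meta-)game.

    Parameters
    ----------
    num_players : int
        Number of players/populations K (>= 1).
    strategy_labels : list of list of str
        Ordered strategy labels per player; sizes define the payoff shape.
    payoffs : list of ndarray
        One K-dimensional payoff tensor per player, axis order player 1..K.
    symmetric_declared : bool
        If True, a symmetry check must pass at construction.
    """

    num_players: int
    strategy_labels: tuple
    payoffs: tuple
    symmetric_declared: bool = False
    name: str = field(default="", compare=False)

    def __post_init__(self):
        if self.num_players < 1:
            raise ValueError("need at least one player")
        labels = tuple(tuple(ls) for ls in self.strategy_labels)
        object.__setattr__(self, "strategy_labels", labels)
        if len(labels) != self.num_players:
            raise ValueError("one strategy-label list per player required")
        shape = tuple(len(ls) for ls in labels)
        if any(n < 1 for n in shape):
            raise ValueError("every strategy set must be non-empty")
        tensors = tuple(np.asarray(M, dtype=float) for M in self.payoffs)
        object.__setattr__(self, "payoffs", tensors)
        if len(tensors) != self.num_players:
            raise ValueError("one payoff tensor per player required")
        for k, M in enumerate(tensors):
            if M.shape != shape:
                raise ValueError(
                    f"payoff tensor of player {k + 1} has shape {M.shape}, "
                    f"expected {shape}"
                )
            if not np.all(np.isfinite(M)):
                raise ValueError(
                    "payoffs must be finite real numbers (the profile chain "
                    "is irreducible only for finite payoffs)"
                )
        if self.symmetric_declared and not check_symmetric(self):
            raise ValueError("game declared symmetric but symmetry check fails")

    @property
    def shape(self) -> tuple:
        return tuple(len(ls) for ls in self.strategy_labels)

    @property
    def num_profiles(self) -> int:
        return int(np.prod(self.shape))

    def profiles(self):
        """Iterate all pure profiles in row-major order (last player fastest)."""
        return itertools.product(*(range(n) for n in self.shape))

    def profile_label(self, profile: Sequence[int]) -> str:
        parts = [self.strategy_labels[k][i] for k, i in enumerate(profile)]
        return "(" + ",".join(parts) + ")" if self.num_players > 1 else parts[0]

    def payoff(self, player: int, profile: Sequence[int]) -> float:
        return payoff_of_profile(self, player, profile)


def payoff_of_profile(game: NormalFormGame, player: int, profile: Sequence[int]) -> float:
    """Payoff M^k(s) of `player` (0-based) at pure profile `profile`."""
    if not 0 <= player < game.num_players:
        raise IndexError(f"player index {player} out of range")
    profile = tuple(int(i) for i in profile)
    if len(profile) != game.num_players:
        raise ValueError("profile length must equal number of players")
    for k, i in enumerate(profile):
        if not 0 <= i < game.shape[k]:
            raise IndexError(f"strategy index {i} out of range for player {k + 1}")
    return float(game.payoffs[player][profile])


def _payoffs_equal(a: float, b: float) -> bool:
    if a == b:
        return True
    if float(a).is_integer() and float(b).is_integer():
        return False
    return math.isclose(a, b, rel_tol=PAYOFF_RTOL, abs_tol=0.0)


def check_symmetric(game: NormalFormGame) -> bool:
    """True iff all strategy sets coincide and payoffs are permutation-covariant.

    A game is symmetric when every player has the same strategy set and, for
    any permutation of the players, permuting the strategy profile permutes
    the payoff profile accordingly.  For K=2 this reduces to B = A^T.
    Integer payoffs are compared exactly, others to relative tolerance.
    """
    labels = game.strategy_labels
    if any(ls != labels[0] for ls in labels[1:]):
        return False
    if game.num_players == 1:
        return True
    for perm in itertools.permutations(range(game.num_players)):
        for profile in game.profiles():
            permuted = tuple(profile[perm[k]] for k in range(game.num_players))
            for k in range(game.num_players):
                # player k at the permuted profile must earn what player
                # perm[k] earned at the original profile
                if not _payoffs_equal(
                    float(game.payoffs[k][permuted]),
                    float(game.payoffs[perm[k]][profile]),
                ):
                    return False
    return True


# ---------------------------------------------------------------------------
# canonical games

def _rps_matrix(margins=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Antisymmetric cyclic matrix: R beats S, S beats P, P beats R."""
    m_rs, m_sp, m_pr = margins
    A = np.zeros((3, 3))
    A[0, 2], A[2, 0] = m_rs, -m_rs   # rock vs scissors
    A[2, 1], A[1, 2] = m_sp, -m_sp   # scissors vs paper
    A[1, 0], A[0, 1] = m_pr, -m_pr   # paper vs rock
    return A


def make_canonical_game(name: str, params: Sequence[float] | None = None) -> NormalFormGame:
    """Build one of the documented canonical games.

    Names: ``rps`` (symmetric zero-sum win/loss/tie = +1/-1/0),
    ``biased_rps`` (antisymmetric cyclic matrix, three positive win margins,
    default (0.5, 0.25, 0.1)), ``battle_of_sexes`` (diagonal (3,2)/(2,3),
    off-diagonal (0,0)), ``matching_pennies`` (zero-sum +/-1), and
    ``coordination`` (diagonal (1,1), off-diagonal (0,0)).
    """
    name = name.lower()
    if name == "rps":
        A = _rps_matrix()
        return NormalFormGame(
            2, [["R", "P", "S"]] * 2, [A, A.T], symmetric_declared=True, name="rps"
        )
    if name == "biased_rps":
        margins = tuple(params) if params is not None else (0.5, 0.25, 0.1)
        if len(margins) != 3 or any(m <= 0 for m in margins):
            raise ValueError("biased_rps needs three positive win margins")
        A = _rps_matrix(margins)
        return NormalFormGame(
            2, [["R", "P", "S"]] * 2, [A, A.T], symmetric_declared=True,
            name="biased_rps",
        )
    if name == "battle_of_sexes":
        A = np.array([[3.0, 0.0], [0.0, 2.0]])
        B = np.array([[2.0, 0.0], [0.0, 3.0]])
        return NormalFormGame(2, [["O", "M"]] * 2, [A, B], name="battle_of_sexes")
    if name == "matching_pennies":
        A = np.array([[1.0, -1.0], [-1.0, 1.0]])
        return NormalFormGame(2, [["H", "T"]] * 2, [A, -A], name="matching_pennies")
    if name == "coordination":
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        return NormalFormGame(
            2, [["A", "B"]] * 2, [A, A.T], symmetric_declared=True,
            name="coordination",
        )
    raise ValueError(f"unknown canonical game: {name!r}")


CANONICAL_GAMES = ("rps", "biased_rps", "battle_of_sexes", "matching_pennies",
                   "coordination")


def random_game(K: int, sizes: Sequence[int], payoff_range: Sequence[float],
                seed: int) -> NormalFormGame:
    """Game with payoffs drawn i.i.d. uniformly from ``payoff_range``.

    Deterministic in ``seed``; a degenerate interval yields a constant game.
    """
    if K < 1:
        raise ValueError("need at least one player")
    sizes = [int(n) for n in sizes]
    if len(sizes) != K or any(n < 1 for n in sizes):
        raise ValueError("sizes must list one positive size per player")
    lo, hi = float(payoff_range[0]), float(payoff_range[1])
    rng = np.random.default_rng(seed)
    shape = tuple(sizes)
    payoffs = [rng.uniform(lo, hi, size=shape) if hi > lo else np.full(shape, lo)
               for _ in range(K)]
    labels = [[f"s{k + 1}_{i}" for i in range(sizes[k])] for k in range(K)]
    return NormalFormGame(K, labels, payoffs, name=f"random(seed={seed})")


def count_two_faces(n: int) -> int:
    """Number of distinct 3-strategy sub-simplices (2-faces) among n strategies.

    This is C(n, 3): the count of strategy triples whose simplex faces one
    would enumerate when visualising dynamics restricted to three strategies.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    return math.comb(n, 3)


# ---------------------------------------------------------------------------
# file I/O
#
# JSON schema: {"players": K, "strategies": [[labels]...],
#               "payoffs": [flattened row-major tensor per player],
#               "symmetric": bool (optional)}
# .nfg dialect: "NFG 1 R" header, quoted title, strategy counts, then the
# payoff list with player 1's strategy varying fastest and the K payoffs
# interleaved at each cell.


def _game_to_jsonable(game: NormalFormGame) -> dict:
    return {
        "players": game.num_players,
        "strategies": [list(ls) for ls in game.strategy_labels],
        "payoffs": [M.ravel(order="C").tolist() for M in game.payoffs],
        "symmetric": bool(game.symmetric_declared),
    }


def _game_from_jsonable(doc: dict) -> NormalFormGame:
    try:
        K = int(doc["players"])
        labels = doc["strategies"]
        flat = doc["payoffs"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed game JSON: missing field {exc}") from exc
    shape = tuple(len(ls) for ls in labels)
    n = int(np.prod(shape)) if shape else 0
    tensors = []
    for k, entries in enumerate(flat):
        for v in entries:
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(
                    f"player {k + 1} payoff {v!r} is not a finite number; "
                    "the profile chain requires finite payoffs"
                )
        if len(entries) != n:
            raise ValueError(
                f"player {k + 1} payoff list has {len(entries)} entries, "
                f"expected {n} for shape {shape}"
            )
        tensors.append(np.asarray(entries, dtype=float).reshape(shape, order="C"))
    return NormalFormGame(K, labels, tensors,
                          symmetric_declared=bool(doc.get("symmetric", False)))


def _write_nfg(game: NormalFormGame, path) -> None:
    lines = [
        'NFG 1 R "evorank game"',
        "{ " + " ".join(f'"Player{k + 1}"' for k in range(game.num_players)) + " } "
        "{ " + " ".join(str(n) for n in game.shape) + " }",
        "",
    ]
    # nfg order: player 1's strategy varies fastest => column-major profiles
    values = []
    for profile in itertools.product(*(range(n) for n in reversed(game.shape))):
        profile = tuple(reversed(profile))
        for k in range(game.num_players):
            values.append(repr(float(game.payoffs[k][profile])))
    lines.append(" ".join(values))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_nfg(path) -> NormalFormGame:
    with open(path) as fh:
        text = fh.read()
    if not text.startswith("NFG 1 R"):
        raise ValueError(f"{path}: not an 'NFG 1 R' payoff file (line 1)")
    # strip quoted strings (title, player names)
    body = re.sub(r'"[^"]*"', " ", text[len("NFG 1 R"):])
    brace_groups = re.findall(r"\{([^{}]*)\}", body)
    if not brace_groups:
        raise ValueError(f"{path}: missing strategy-count block")
    # last brace group holds the strategy counts; earlier ones are player names
    sizes = [int(tok) for tok in brace_groups[-1].split()]
    K = len(sizes)
    tail = body[body.rfind("}") + 1:]
    tokens = tail.split()
    try:
        numbers = [float(tok) for tok in tokens]
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric payoff token ({exc})") from exc
    n = int(np.prod(sizes))
    if len(numbers) != n * K:
        raise ValueError(
            f"{path}: found {len(numbers)} payoff numbers, expected "
            f"{n * K} for {K} players with sizes {sizes}"
        )
    if not all(math.isfinite(v) for v in numbers):
        raise ValueError(f"{path}: non-finite payoff; finite payoffs required")
    shape = tuple(sizes)
    tensors = [np.empty(shape) for _ in range(K)]
    pos = 0
    for profile in itertools.product(*(range(n) for n in reversed(shape))):
        profile = tuple(reversed(profile))
        for k in range(K):
            tensors[k][profile] = numbers[pos]
            pos += 1
    labels = [[f"s{k + 1}_{i}" for i in range(sizes[k])] for k in range(K)]
    return NormalFormGame(K, labels, tensors)


def write_game(game: NormalFormGame, path, format: str = "json") -> None:
    """Serialize a game to ``json`` or Gambit-style ``nfg`` text."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_game_to_jsonable(game), fh, indent=1)
            fh.write("\n")
    elif format == "nfg":
        _write_nfg(game, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_game(path, format: str = "json") -> NormalFormGame:
    """Read a game from ``json`` or Gambit-style ``nfg`` text."""
    if format == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{exc.lineno}: invalid JSON: {exc.msg}") from exc
        return _game_from_jsonable(doc)
    if format == "nfg":
        return _read_nfg(path)
    raise ValueError(f"unknown format {format!r}")
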