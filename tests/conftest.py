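import numpy as np
import pytest

from evorank import make_canonical_game, random_game

CANONICAL = ["rps", "biased_rps", "battle_of_sexes", "matching_pennies",
             "coordination"]


@pytest.fixture(scope="session")
def canonical_games():
    return {name: make_canonical_game(name) for name in CANONICAL}


def random_game_corpus(n_games, seed, max_players=3, max_size=4, min_size=2,
                       payoff_range=(-1.0, 1.0)):
    """Seeded batch of random games with varying K and strategy-set sizes."""
    rng = np.random.default_rng(seed)
    games = []
    for i in range(n_games):
        K = int(rng.integers(1, max_players + 1))
        sizes = [int(rng.integers(min_size, max_size + 1)) for _ in range(K)]
        games.append(random_game(K, sizes, payoff_range,
                                 seed=int(rng.integers(0, 2**31 - 1))))
    return games
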