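import numpy as np
import pytest

from tokengame import (
    GameConfig,
    GameData,
    GroupAssignment,
    STUDY_CONFIG,
    RngSpec,
    toy4_game,
)


@pytest.fixture(scope="session")
def toy4() -> GameData:
    return toy4_game()


@pytest.fixture(scope="session")
def rng() -> RngSpec:
    return RngSpec(20260922)


@pytest.fixture(scope="session")
def null_game(rng) -> GameData:
    """One seeded giving-at-random game at study scale."""
    from tokengame import simulate_null_game
    return simulate_null_game(STUDY_CONFIG, rng)


def random_small_game(seed: int, max_players: int = 6, max_rounds: int = 8) -> GameData:
    """A uniformly random valid game with 2 groups, for oracle cross-checks."""
    gen = np.random.default_rng(seed)
    g1 = int(gen.integers(1, max_players // 2 + 1))
    g2 = int(gen.integers(1, max_players - g1 + 1)) if max_players - g1 >= 1 else 1
    n = g1 + g2
    T = int(gen.integers(0, max_rounds + 1))
    config = GameConfig(n_players=n, group_sizes=(g1, g2), n_rounds=T,
                        initial_tokens=max_rounds, allow_self_giving=True)
    groups = GroupAssignment.default_two_groups(config)
    receivers = gen.integers(0, n, size=(T, n))
    return GameData(config, groups, receivers)
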