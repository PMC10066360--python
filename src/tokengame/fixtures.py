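"""Deterministic fixture games.

Four families:

* TOY-4 — a fixed 4-player, 3-round game with hand-countable exchange
  matrices, used throughout the tests as the worked micro-example.
* a study-scale null game (14 players, two groups of 7, 40 rounds, seeded);
* a "locked-pair" game: null background with two outgroup players overridden
  to give to each other every round — an extreme reciprocal outgroup dyad;
* an ingroup-biased game generated by biased agents (default weights:
  self 1, ingroup 3, outgroup 1).
"""

from __future__ import annotations

from pathlib import Path

from .game import GameConfig, GameData, GroupAssignment, STUDY_CONFIG, write_game
from .rng import RngSpec
from .simulate import AgentPolicy, simulate_agent_game, simulate_null_game

__all__ = [
    "TOY4_CONFIG",
    "toy4_game",
    "null_fixture_game",
    "locked_pair_game",
    "ingroup_biased_game",
    "make_fixtures",
]

TOY4_CONFIG = GameConfig(n_players=4, group_sizes=(2, 2), n_rounds=3,
                         initial_tokens=5, allow_self_giving=True)

# (round, giver, receiver); players 1,2 in group A, 3,4 in group B.
_TOY4_ROWS = [
    (1, 1, 2), (1, 2, 1), (1, 3, 1), (1, 4, 4),
    (2, 1, 2), (2, 2, 1), (2, 3, 1), (2, 4, 3),
    (3, 1, 3), (3, 2, 2), (3, 3, 1), (3, 4, 3),
]


def toy4_game() -> GameData:
    """The fixed TOY-4 micro-game: 4 players, 2 groups of 2, 3 rounds."""
    groups = GroupAssignment.from_mapping({1: "A", 2: "A", 3: "B", 4: "B"}, 4)
    return GameData.from_records(TOY4_CONFIG, groups, _TOY4_ROWS)


def null_fixture_game(seed: int, config: GameConfig = STUDY_CONFIG,
                      replicate: int = 0) -> GameData:
    """A seeded giving-at-random game at study scale."""
    return simulate_null_game(config, RngSpec(seed), replicate=replicate)


def locked_pair_game(seed: int, pair: tuple[int, int] = (3, 8),
                     config: GameConfig = STUDY_CONFIG) -> GameData:
    """Null background with one outgroup pair exchanging every round.

    The two players (default ids 3 and 8, one from each group under the
    default assignment) give exclusively to each other for the whole game,
    so their mutual cumulative counts equal t at every round — an extreme
    reciprocal outgroup dyad on top of otherwise random behaviour.
    """
    base = simulate_null_game(config, RngSpec(seed), replicate=0)
    a, b = pair
    if base.groups.same_group(a, b):
        raise ValueError("locked pair must span the two groups")
    recv = base.receivers.copy()
    recv[:, a - 1] = b - 1
    recv[:, b - 1] = a - 1
    return GameData(base.config, base.groups, recv)


def ingroup_biased_game(seed: int, strength: float = 3.0,
                        config: GameConfig = STUDY_CONFIG,
                        replicate: int = 0) -> GameData:
    """Game of biased agents preferring the ingroup by the given weight ratio.

    Every player uses weights (self 1, ingroup ``strength``, outgroup 1);
    ``strength`` = 1 recovers the null.
    """
    policy = AgentPolicy(kind="biased", w_self=1.0, w_ingroup=strength, w_outgroup=1.0)
    return simulate_agent_game(config, [policy] * config.n_players,
                               RngSpec(seed), replicate=replicate)


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the four fixture games (players/allocations/config files each).

    Deterministic: the same seed always regenerates identical files.
    """
    out = Path(out_dir)
    written = {}
    for name, game in (
        ("toy4", toy4_game()),
        ("null_game", null_fixture_game(seed)),
        ("locked_pair", locked_pair_game(seed)),
        ("ingroup_biased", ingroup_biased_game(seed)),
    ):
        paths = write_game(game, out / name)
        written[name] = paths["allocations"].parent
    return written
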