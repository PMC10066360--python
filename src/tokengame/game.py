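"""Data model, validation and I/O for round-based token-exchange games.

A game consists of ``n_players`` players split into groups. Every round each
player allocates exactly one token to some player (possibly themself, when
self-giving is allowed). The observed log is therefore a function
(round, giver) -> receiver, and the quantity the downstream models work with
is the cumulative exchange count ``Y[i, j]``: the number of tokens player *i*
has received from player *j* up to and including a given round.

Player ids are 1-based consecutive integers; rounds are 1-based, with round
index ``t = 0`` meaning "before any interaction". Group labels are opaque
strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GameConfig",
    "GroupAssignment",
    "Allocation",
    "GameData",
    "ExchangeMatrix",
    "GameValidationError",
    "STUDY_CONFIG",
    "load_game",
    "load_config",
    "write_game",
    "cumulative_matrix",
    "token_balances",
]


class GameValidationError(ValueError):
    """Raised when a game log or configuration violates the game rules."""


@dataclass(frozen=True)
class GameConfig:
    """Static parameters of a token-exchange game.

    The standard study design is 14 players in two groups of 7, 40 rounds,
    40 initial tokens per player, self-giving allowed — with one token given
    per player per round, a player can then never run out of tokens.
    """

    n_players: int
    group_sizes: tuple[int, ...]
    n_rounds: int
    initial_tokens: int
    allow_self_giving: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_sizes", tuple(int(g) for g in self.group_sizes))
        if self.n_players <= 0:
            raise GameValidationError("n_players must be positive")
        if self.n_rounds < 0:
            raise GameValidationError("n_rounds must be non-negative")
        if self.initial_tokens < 0:
            raise GameValidationError("initial_tokens must be non-negative")
        if any(g <= 0 for g in self.group_sizes):
            raise GameValidationError("group sizes must be positive")
        if sum(self.group_sizes) != self.n_players:
            raise GameValidationError("group sizes must sum to n_players")


STUDY_CONFIG = GameConfig(
    n_players=14, group_sizes=(7, 7), n_rounds=40, initial_tokens=40,
    allow_self_giving=True,
)


class Allocation(NamedTuple):
    """One token allocation: in ``round``, ``giver`` gave a token to ``receiver``."""

    round: int
    giver: int
    receiver: int


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping from player id (1-based) to an opaque group label."""

    labels: tuple[str, ...]  # labels[i-1] is the group of player i

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, str], n_players: int) -> "GroupAssignment":
        if sorted(mapping) != list(range(1, n_players + 1)):
            raise GameValidationError("unknown player: ids must be 1..n_players, each exactly once")
        return cls(tuple(str(mapping[i]) for i in range(1, n_players + 1)))

    @classmethod
    def default_two_groups(cls, config: GameConfig,
                           names: Sequence[str] = ("A", "B")) -> "GroupAssignment":
        labels: list[str] = []
        for name, size in zip(names, config.group_sizes):
            labels.extend([name] * size)
        return cls(tuple(labels))

    @property
    def n_players(self) -> int:
        return len(self.labels)

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return tuple(seen)

    def label_of(self, player: int) -> str:
        return self.labels[player - 1]

    def same_group(self, i: int, j: int) -> bool:
        return self.labels[i - 1] == self.labels[j - 1]

    def codes(self) -> np.ndarray:
        """Integer group code per player (0-based array of length n_players)."""
        names = {lab: k for k, lab in enumerate(self.group_names)}
        return np.array([names[lab] for lab in self.labels], dtype=np.int64)

    def validate_against(self, config: GameConfig) -> None:
        if self.n_players != config.n_players:
            raise GameValidationError("group assignment size does not match config")
        sizes = sorted(np.bincount(self.codes()).tolist())
        if sizes != sorted(config.group_sizes):
            raise GameValidationError("group sizes do not match config")


@dataclass(frozen=True)
class GameData:
    """A validated game: configuration, group assignment and allocation log.

    The log is held as a dense ``(n_rounds, n_players)`` array of 0-based
    receiver indices — entry ``[t-1, j-1]`` is the receiver chosen by giver
    *j* in round *t* — which encodes the one-allocation-per-giver-per-round
    constraint structurally and keeps Monte-Carlo loops cheap.
    """

    config: GameConfig
    groups: GroupAssignment
    receivers: np.ndarray = field(repr=False)  # shape (n_rounds, n_players), 0-based

    def __post_init__(self) -> None:
        self.groups.validate_against(self.config)
        r = np.asarray(self.receivers, dtype=np.int64)
        object.__setattr__(self, "receivers", r)
        if r.shape != (self.config.n_rounds, self.config.n_players):
            raise GameValidationError("incomplete round: allocation log has wrong shape")
        if r.size and (r.min() < 0 or r.max() >= self.config.n_players):
            raise GameValidationError("unknown player in allocation log")
        if not self.config.allow_self_giving and r.size:
            givers = np.arange(self.config.n_players)
            if np.any(r == givers[None, :]):
                raise GameValidationError("self-giving disallowed")
        r.setflags(write=False)

    @classmethod
    def from_records(
        cls,
        config: GameConfig,
        groups: GroupAssignment,
        records: Iterable[tuple[int, int, int]],
    ) -> "GameData":
        """Build from (round, giver, receiver) triples, in any order."""
        n, T = config.n_players, config.n_rounds
        recv = np.full((T, n), -1, dtype=np.int64)
        count = 0
        for rnd, giver, receiver in records:
            rnd, giver, receiver = int(rnd), int(giver), int(receiver)
            if not (1 <= rnd <= T):
                raise GameValidationError(f"round out of range: {rnd}")
            if not (1 <= giver <= n) or not (1 <= receiver <= n):
                raise GameValidationError(f"unknown player in round {rnd}")
            if giver == receiver and not config.allow_self_giving:
                raise GameValidationError("self-giving disallowed")
            if recv[rnd - 1, giver - 1] != -1:
                raise GameValidationError(
                    f"multiple allocations per round: giver {giver} in round {rnd}")
            recv[rnd - 1, giver - 1] = receiver - 1
            count += 1
        if count != n * T or (recv == -1).any():
            raise GameValidationError("incomplete round: every (round, giver) pair needs one allocation")
        return cls(config, groups, recv)

    @property
    def n_players(self) -> int:
        return self.config.n_players

    @property
    def n_rounds(self) -> int:
        return self.config.n_rounds

    @property
    def allocations(self) -> pd.DataFrame:
        """The log as a DataFrame with columns round, giver_id, receiver_id."""
        T, n = self.receivers.shape
        rounds = np.repeat(np.arange(1, T + 1), n)
        givers = np.tile(np.arange(1, n + 1), T)
        return pd.DataFrame({
            "round": rounds,
            "giver_id": givers,
            "receiver_id": self.receivers.reshape(-1) + 1,
        })

    def allocation_tuples(self) -> list[Allocation]:
        return [Allocation(int(r), int(g), int(v))
                for r, g, v in self.allocations.itertuples(index=False)]


@dataclass(frozen=True)
class ExchangeMatrix:
    """Cumulative received-count matrix at round ``t``.

    ``Y[i-1, j-1]`` is the number of tokens player *i* has received from
    player *j* up to and including round *t* (self-giving on the diagonal).
    Every giver's column sums to ``t``.
    """

    t: int
    Y: np.ndarray

    def received_from(self, i: int, j: int) -> int:
        return int(self.Y[i - 1, j - 1])


def _check_round(game: GameData, t: int) -> None:
    if not (0 <= t <= game.n_rounds):
        raise GameValidationError(f"round out of range: {t}")


def cumulative_matrix(game: GameData, t: int) -> ExchangeMatrix:
    """Cumulative exchange matrix after round ``t`` (``t = 0`` gives zeros)."""
    _check_round(game, t)
    n = game.n_players
    Y = np.zeros((n, n), dtype=np.int64)
    if t > 0:
        recv = game.receivers[:t]  # (t, n)
        np.add.at(Y, (recv.reshape(-1), np.tile(np.arange(n), t)), 1)
    return ExchangeMatrix(t=t, Y=Y)


def cumulative_stack(game: GameData) -> np.ndarray:
    """All cumulative matrices at once: shape (n_rounds, n, n), entry [t-1] = Y at round t."""
    T, n = game.receivers.shape
    inc = np.zeros((T, n, n), dtype=np.int64)
    if T:
        t_grid = np.repeat(np.arange(T), n)
        g_grid = np.tile(np.arange(n), T)
        inc[t_grid, game.receivers.reshape(-1), g_grid] = 1
    return np.cumsum(inc, axis=0)


def token_balances(game: GameData, t: int) -> np.ndarray:
    """Token balance of every player after round ``t``.

    balance_i = initial_tokens - t + (tokens received by i up to t, self
    included); a self-given token is a net no-op. Total balance is conserved
    at n_players * initial_tokens.
    """
    _check_round(game, t)
    received = cumulative_matrix(game, t).Y.sum(axis=1)
    return game.config.initial_tokens - t + received


# ---------------------------------------------------------------------------
# File I/O: players.csv (player_id,group), allocations.csv
# (round,giver_id,receiver_id) and config.yaml.

def load_config(path: str | Path) -> GameConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return GameConfig(
        n_players=int(raw["n_players"]),
        group_sizes=tuple(int(g) for g in raw["group_sizes"]),
        n_rounds=int(raw["n_rounds"]),
        initial_tokens=int(raw["initial_tokens"]),
        allow_self_giving=bool(raw.get("allow_self_giving", True)),
    )


def load_game(players_path: str | Path, allocations_path: str | Path,
              config: GameConfig) -> GameData:
    """Load and fully validate a game from its two CSV files."""
    players = pd.read_csv(players_path)
    for col in ("player_id", "group"):
        if col not in players.columns:
            raise GameValidationError(f"players file missing column {col!r}")
    groups = GroupAssignment.from_mapping(
        dict(zip(players["player_id"].astype(int), players["group"].astype(str))),
        config.n_players,
    )
    alloc = pd.read_csv(allocations_path)
    for col in ("round", "giver_id", "receiver_id"):
        if col not in alloc.columns:
            raise GameValidationError(f"allocations file missing column {col!r}")
    records = zip(alloc["round"].astype(int), alloc["giver_id"].astype(int),
                  alloc["receiver_id"].astype(int))
    return GameData.from_records(config, groups, records)


def write_game(game: GameData, out_dir: str | Path) -> dict[str, Path]:
    """Write players.csv, allocations.csv and config.yaml; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "players": out / "players.csv",
        "allocations": out / "allocations.csv",
        "config": out / "config.yaml",
    }
    pd.DataFrame({
        "player_id": np.arange(1, game.n_players + 1),
        "group": list(game.groups.labels),
    }).to_csv(paths["players"], index=False)
    game.allocations.to_csv(paths["allocations"], index=False)
    cfg = game.config
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({
            "n_players": cfg.n_players,
            "group_sizes": list(cfg.group_sizes),
            "n_rounds": cfg.n_rounds,
            "initial_tokens": cfg.initial_tokens,
            "allow_self_giving": cfg.allow_self_giving,
        }, fh, sort_keys=False)
    return paths
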