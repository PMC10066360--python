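"""Agent-based game simulators.

Three generators are provided:

* :func:`simulate_null_game` — the giving-at-random null: every round, every
  player picks a receiver uniformly over all players *including themself*.
  With ``n`` players the expected cumulative count for any ordered pair at
  round ``t`` is therefore ``t / n``.
* :func:`replace_players` — semi-synthetic games: the observed log is kept
  verbatim except that the designated players' allocations are re-drawn
  uniformly at random (memoryless, self included). Tokens *received by* the
  replaced players from everyone else are untouched.
* :func:`simulate_agent_game` — behavioural agents (biased group/self
  weights, or a most-frequent-giver reciprocator) used for power and
  parameter-recovery studies; these policies are a testing extension, not a
  model of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .game import GameConfig, GameData, GroupAssignment, GameValidationError
from .rng import RngSpec

__all__ = [
    "AgentPolicy",
    "simulate_null_game",
    "replace_players",
    "simulate_agent_game",
]


@dataclass(frozen=True)
class AgentPolicy:
    """Per-player giving policy.

    kind:
        ``uniform_random`` — uniform over all players (the null agent);
        ``biased`` — receiver weight depends only on the relation to the
        giver: ``w_self`` for the giver themself, ``w_ingroup`` for each
        same-group player, ``w_outgroup`` for each outgroup player;
        ``reciprocator`` — gives to the player it has received most tokens
        from so far (ties uniform at random), falling back to ``fallback``
        (default uniform) while it has received nothing.
    """

    kind: str = "uniform_random"
    w_self: float = 1.0
    w_ingroup: float = 1.0
    w_outgroup: float = 1.0
    fallback: str = "uniform_random"

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_random", "biased", "reciprocator"):
            raise GameValidationError(f"invalid policy kind {self.kind!r}")
        if self.kind == "biased":
            w = (self.w_self, self.w_ingroup, self.w_outgroup)
            if any(x < 0 for x in w) or not any(x > 0 for x in w):
                raise GameValidationError(
                    "invalid policy: biased weights must be non-negative, not all zero")


def _default_groups(config: GameConfig,
                    groups: GroupAssignment | None) -> GroupAssignment:
    if groups is not None:
        groups.validate_against(config)
        return groups
    names = [chr(ord("A") + k) for k in range(len(config.group_sizes))]
    return GroupAssignment.default_two_groups(config, names)


def simulate_null_game(config: GameConfig, rng: RngSpec, replicate: int = 0,
                       groups: GroupAssignment | None = None) -> GameData:
    """One fully synthetic giving-at-random game.

    Every (round, giver) receiver is i.i.d. uniform over all ``n_players``
    players, self included. Deterministic given (rng.seed, replicate).
    """
    groups = _default_groups(config, groups)
    gen = rng.generator("null", replicate)
    recv = gen.integers(0, config.n_players, size=(config.n_rounds, config.n_players))
    return GameData(config, groups, recv)


def replace_players(game: GameData, player_ids: Iterable[int], rng: RngSpec,
                    replicate: int = 0) -> GameData:
    """Semi-synthetic game with the given players replaced by null agents.

    Allocations by every other player are copied verbatim; each replaced
    player's receiver is re-drawn uniformly over all players (self included)
    independently every round. Replacement preserves the one-token-per-round
    structure, unlike deleting a player's rows.
    """
    ids = sorted({int(i) for i in player_ids})
    n = game.n_players
    for i in ids:
        if not (1 <= i <= n):
            raise GameValidationError(f"unknown player: {i}")
    recv = game.receivers.copy()
    if ids:
        gen = rng.generator("replace", replicate)
        cols = np.array([i - 1 for i in ids])
        recv[:, cols] = gen.integers(0, n, size=(game.n_rounds, len(cols)))
    return GameData(game.config, game.groups, recv)


def _policy_probs(policy: AgentPolicy, giver0: int, codes: np.ndarray) -> np.ndarray:
    """Receiver distribution for a uniform or biased policy (0-based giver)."""
    n = len(codes)
    if policy.kind == "uniform_random":
        return np.full(n, 1.0 / n)
    w = np.where(codes == codes[giver0], policy.w_ingroup, policy.w_outgroup).astype(float)
    w[giver0] = policy.w_self
    total = w.sum()
    if total <= 0:
        raise GameValidationError("invalid policy: weights sum to zero for a giver")
    return w / total


def simulate_agent_game(config: GameConfig, policies: Sequence[AgentPolicy],
                        rng: RngSpec, replicate: int = 0,
                        groups: GroupAssignment | None = None) -> GameData:
    """Simulate a game where each player follows its own :class:`AgentPolicy`.

    Rounds are sequential so that reciprocators can react to what they have
    received in earlier rounds; with no reciprocators the draws reduce to
    independent per-round sampling from fixed distributions.
    """
    if len(policies) != config.n_players:
        raise GameValidationError("one policy per player required")
    groups = _default_groups(config, groups)
    codes = groups.codes()
    n, T = config.n_players, config.n_rounds
    gen = rng.generator("agent", replicate)

    static_probs = [
        _policy_probs(p, g, codes) if p.kind != "reciprocator" else None
        for g, p in enumerate(policies)
    ]
    fallback_probs = [
        _policy_probs(AgentPolicy(kind=p.fallback), g, codes)
        if p.kind == "reciprocator" else None
        for g, p in enumerate(policies)
    ]

    received = np.zeros((n, n), dtype=np.int64)  # received[i, j]: i got from j
    recv = np.empty((T, n), dtype=np.int64)
    for t in range(T):
        for g in range(n):
            pol = policies[g]
            if pol.kind != "reciprocator":
                recv[t, g] = gen.choice(n, p=static_probs[g])
            else:
                got = received[g]  # tokens g received, by giver
                if got.sum() == 0:
                    recv[t, g] = gen.choice(n, p=fallback_probs[g])
                else:
                    best = np.flatnonzero(got == got.max())
                    recv[t, g] = best[gen.integers(len(best))]
        np.add.at(received, (recv[t], np.arange(n)), 1)
    return GameData(config, groups, recv)
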