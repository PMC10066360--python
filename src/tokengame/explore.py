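"""Descriptive statistics of a game: where tokens come from and how much
pairs of players reciprocate.

Tokens received are partitioned into three sources — ingroup (other players
in the giver's group), outgroup, and self — and give/receive counts are
tabulated per ordered player pair. Reciprocity within a scope (ingroup or
outgroup) is summarised by the Pearson correlation between tokens given and
tokens received over the symmetric pair set.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .game import GameData, GameValidationError, cumulative_matrix

__all__ = [
    "ProportionTriple",
    "received_proportions",
    "proportions_per_round",
    "pair_table",
    "reciprocity_correlation",
    "reciprocated_tokens",
]


class ProportionTriple(NamedTuple):
    """Fractions of all tokens received from ingroup, outgroup and self.

    The three values partition unity; "ingroup" excludes self-giving, which
    is its own category.
    """

    ingroup: float
    outgroup: float
    self_: float


def _same_group_matrix(game: GameData) -> np.ndarray:
    codes = game.groups.codes()
    return codes[:, None] == codes[None, :]


def received_proportions(game: GameData, t: int) -> ProportionTriple:
    """Proportion of all tokens received from ingroup / outgroup / self at round ``t``."""
    if t < 1:
        raise GameValidationError("undefined proportions: no tokens allocated before round 1")
    Y = cumulative_matrix(game, t).Y
    total = game.n_players * t
    self_tokens = np.trace(Y)
    same = _same_group_matrix(game)
    ingroup = int(Y[same].sum()) - int(self_tokens)
    outgroup = int(Y[~same].sum())
    return ProportionTriple(ingroup / total, outgroup / total, self_tokens / total)


def proportions_per_round(game: GameData) -> pd.DataFrame:
    """Received proportions at every round: columns t, ingroup, outgroup, self."""
    rows = []
    for t in range(1, game.n_rounds + 1):
        p = received_proportions(game, t)
        rows.append((t, p.ingroup, p.outgroup, p.self_))
    return pd.DataFrame(rows, columns=["t", "ingroup", "outgroup", "self"])


def pair_table(game: GameData, t: int, include_self: bool = False) -> pd.DataFrame:
    """Give/receive counts per ordered player pair at round ``t``.

    One row per ordered pair (i, j), i != j: ``given`` is the count i gave j
    (``Y[j, i]``) and ``received`` the count i received from j (``Y[i, j]``);
    the table is symmetric in the sense that row (i, j, g, r) implies row
    (j, i, r, g). Self rows (i, i) are appended only when ``include_self``.
    """
    Y = cumulative_matrix(game, t).Y
    same = _same_group_matrix(game)
    n = game.n_players
    rows = []
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i == j and not include_self:
                continue
            rows.append((
                i, j,
                int(Y[j - 1, i - 1]), int(Y[i - 1, j - 1]),
                bool(same[i - 1, j - 1]), i == j,
            ))
    return pd.DataFrame(rows, columns=["i", "j", "given", "received",
                                       "same_group", "is_self"])


def reciprocity_correlation(game: GameData, scope: str, t: int,
                            include_self: bool = False) -> float:
    """Pearson correlation between tokens given and received within a scope.

    ``scope`` is ``"ingroup"`` or ``"outgroup"``. Values near 1 mean pairs
    return roughly what they get. Self-pairs sit exactly on the diagonal and
    are excluded by default (they can only inflate the ingroup value).
    Returns NaN when either axis has zero variance (degenerate correlation).
    """
    if scope not in ("ingroup", "outgroup"):
        raise ValueError(f"scope must be 'ingroup' or 'outgroup', got {scope!r}")
    table = pair_table(game, t, include_self=include_self and scope == "ingroup")
    mask = table["same_group"] if scope == "ingroup" else ~table["same_group"]
    sub = table[mask]
    if len(sub) < 2:
        return float("nan")
    x = sub["given"].to_numpy(float)
    y = sub["received"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # degenerate: zero variance on an axis
    return float(np.corrcoef(x, y)[0, 1])


def reciprocated_tokens(game: GameData, t: int | None = None) -> pd.DataFrame:
    """Per-player count of reciprocated tokens: sum over partners of
    min(given, received).

    A descriptive extra for profiling individual players; it feeds no model.
    """
    t = game.n_rounds if t is None else t
    Y = cumulative_matrix(game, t).Y
    given = Y.T
    m = np.minimum(Y, given)
    np.fill_diagonal(m, 0)
    return pd.DataFrame({
        "player_id": np.arange(1, game.n_players + 1),
        "reciprocated": m.sum(axis=1),
    })
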