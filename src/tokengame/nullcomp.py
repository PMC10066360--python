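"""Monte-Carlo null reference distributions for fitted coefficients.

The sampling distribution of the dyadic OLS coefficients under the
giving-at-random null is obtained by brute force: simulate K null games with
the observed game's configuration, fit the chosen model variant at the
requested rounds in each, and keep every estimate. Observed coefficients are
then judged against the empirical 2.5-97.5% band and a two-sided add-one
Monte-Carlo p-value,

    p = min(1, 2 * min[(1 + #{draw <= obs}) / (K + 1),
                       (1 + #{draw >= obs}) / (K + 1)])

which is strictly positive with floor 2 / (K + 1). Classical OLS standard
errors are deliberately not used anywhere: the one-token-per-round
constraint makes the observations dependent, so this empirical reference is
the inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .game import GameConfig, GameData
from .regression import VARIANTS, _canon, fit_trajectory
from .rng import RngSpec
from .simulate import simulate_null_game

__all__ = [
    "NullDistribution",
    "ComparisonReport",
    "null_reference",
    "percentile_band",
    "empirical_p",
    "compare",
]


@dataclass(frozen=True)
class NullDistribution:
    """K coefficient draws per (term, round) from simulated null games.

    ``draws`` has shape (K, n_rounds_covered, n_terms). Regenerating with the
    same (config, variant, rounds, K, seed) reproduces the draws exactly.
    """

    config: GameConfig
    variant: str
    rounds: np.ndarray
    terms: tuple[str, ...]
    seed: int
    draws: np.ndarray = field(repr=False)

    @property
    def n_replicates(self) -> int:
        return self.draws.shape[0]

    def _locate(self, term: str, t: int) -> tuple[int, int]:
        if term not in self.terms:
            raise KeyError(f"no reference for term/round: term {term!r} not in {self.terms}")
        where = np.flatnonzero(self.rounds == t)
        if not where.size:
            raise KeyError(f"no reference for term/round: round {t} not covered")
        return int(where[0]), self.terms.index(term)

    def term_draws(self, term: str, t: int) -> np.ndarray:
        r, k = self._locate(term, t)
        return self.draws[:, r, k]

    def to_frame(self) -> pd.DataFrame:
        """Long format: replicate, t, term, estimate."""
        K, R, P = self.draws.shape
        return pd.DataFrame({
            "replicate": np.repeat(np.arange(1, K + 1), R * P),
            "t": np.tile(np.repeat(self.rounds, P), K),
            "term": np.tile(list(self.terms), K * R),
            "estimate": self.draws.reshape(-1),
        })

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ComparisonReport:
    """Observed coefficients joined with null bands and empirical p-values.

    ``frame`` columns: t, term, observed, lower, upper, p, outside.
    """

    variant: str
    level: float
    frame: pd.DataFrame

    def outside_rate(self) -> float:
        return float(self.frame["outside"].mean())

    def save_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def null_reference(config: GameConfig, variant: str, rounds: Sequence[int],
                   n_replicates: int, rng: RngSpec) -> NullDistribution:
    """Simulate ``n_replicates`` null games and collect fitted coefficients.

    Replicate k uses the independent substream ("null", k), so the draw set
    is reproducible and independent of evaluation order.
    """
    variant = _canon(variant)
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a reference distribution")
    terms = VARIANTS[variant]
    rounds_arr = np.asarray(sorted(int(t) for t in rounds))
    draws = np.empty((n_replicates, rounds_arr.size, len(terms)))
    for k in range(n_replicates):
        g = simulate_null_game(config, rng, replicate=k)
        traj = fit_trajectory(g, variant, rounds_arr)
        for p, term in enumerate(terms):
            draws[k, :, p] = traj.estimates[term]
    return NullDistribution(config=config, variant=variant, rounds=rounds_arr,
                            terms=terms, seed=rng.seed, draws=draws)


def _nearest_rank(sorted_draws: np.ndarray, q: float) -> float:
    """Nearest-order-statistic quantile: index round(q * (K - 1)), half up."""
    K = len(sorted_draws)
    idx = int(np.floor(q * (K - 1) + 0.5))
    return float(sorted_draws[min(max(idx, 0), K - 1)])


def percentile_band(dist: NullDistribution, term: str, t: int,
                    level: float = 0.95) -> tuple[float, float]:
    """Empirical central band at the given coverage level.

    Uses the nearest-order-statistic rule (no interpolation), so bands are
    bit-reproducible given a seed. ``level = 0.95`` returns the empirical
    2.5% and 97.5% quantiles.
    """
    draws = np.sort(dist.term_draws(term, t))
    lo_q = (1.0 - level) / 2.0
    return _nearest_rank(draws, lo_q), _nearest_rank(draws, 1.0 - lo_q)


def empirical_p(dist: NullDistribution, term: str, t: int, observed: float) -> float:
    """Two-sided add-one Monte-Carlo p-value of an observed coefficient."""
    draws = dist.term_draws(term, t)
    K = len(draws)
    p_lo = (1 + int(np.sum(draws <= observed))) / (K + 1)
    p_hi = (1 + int(np.sum(draws >= observed))) / (K + 1)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def compare(game: GameData, dist: NullDistribution,
            variant: str | None = None, level: float = 0.95) -> ComparisonReport:
    """Judge a game's fitted coefficients against a null reference.

    Fits the reference's variant at the reference's rounds and reports, per
    (term, round): the observed estimate, the null band at ``level``, the
    empirical p-value, and whether the observation falls outside the band.
    """
    variant = _canon(variant or dist.variant)
    if variant != dist.variant:
        raise ValueError(
            f"incompatible reference: distribution is for {dist.variant!r}, requested {variant!r}")
    if game.config.n_players != dist.config.n_players or \
            tuple(game.config.group_sizes) != tuple(dist.config.group_sizes):
        raise ValueError("incompatible reference: game and null configs differ")
    traj = fit_trajectory(game, variant, dist.rounds)
    rows = []
    for r, t in enumerate(dist.rounds):
        for term in dist.terms:
            obs = float(traj.estimates[term][r])
            lo, hi = percentile_band(dist, term, int(t), level)
            rows.append((int(t), term, obs, lo, hi,
                         empirical_p(dist, term, int(t), obs),
                         obs < lo or obs > hi))
    frame = pd.DataFrame(rows, columns=["t", "term", "observed", "lower",
                                        "upper", "p", "outside"])
    return ComparisonReport(variant=variant, level=level, frame=frame)
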