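"""Dyadic least-squares models of cumulative token exchange.

At a round t the response for the ordered pair (i, j), i != j, is
``Y_ijt`` — tokens i has received from j by round t. The full model is

    Y_ijt = alpha_t + rho_t * Y_jit + gamma_t * G_ij + delta_t * G_ij * Y_jit

where ``Y_jit`` is the reversed count (tokens i gave j) and ``G_ij`` is 1
when i and j are in different groups. Positive ``rho`` indicates
reciprocity; negative ``gamma`` indicates ingroup favouritism; ``delta``
lets the reciprocity effect differ across the group boundary. Four variants
are fitted: reciprocity-only, group-only, additive, and interaction — always
with an intercept.

Estimation is ordinary least squares with no error-distribution assumption;
because the observations are structurally dependent (each giver hands out
exactly one token per round), classical standard errors are not produced
here — inference is delegated to comparison against an agent-based null
(see :mod:`tokengame.nullcomp`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .game import GameData, GameValidationError, cumulative_matrix, cumulative_stack

__all__ = [
    "VARIANTS",
    "variant_terms",
    "DyadicDataset",
    "FitResult",
    "CoefficientTrajectory",
    "build_design",
    "fit_ols",
    "fit_trajectory",
]

# Model variants and their coefficient names (intercept always included).
VARIANTS: dict[str, tuple[str, ...]] = {
    "reciprocity": ("alpha", "rho"),
    "group": ("alpha", "gamma"),
    "additive": ("alpha", "rho", "gamma"),
    "interaction": ("alpha", "rho", "gamma", "delta"),
}

# Tolerated aliases for the variant names.
_ALIASES = {
    "reciprocity_only": "reciprocity",
    "group_only": "group",
}


def _canon(variant: str) -> str:
    v = _ALIASES.get(variant, variant)
    if v not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    return v


def variant_terms(variant: str) -> tuple[str, ...]:
    """Coefficient names of a variant, e.g. additive -> (alpha, rho, gamma)."""
    return VARIANTS[_canon(variant)]


@dataclass(frozen=True)
class DyadicDataset:
    """Ordered-pair design table at one round.

    ``frame`` has one row per ordered pair (i, j), i != j — so
    n_players * (n_players - 1) rows — with columns ``i, j, y`` (response
    Y_ijt), ``y_rev`` (Y_jit) and ``g`` (1 = different groups).
    """

    t: int
    variant: str
    frame: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def design_matrix(self) -> np.ndarray:
        """Columns in coefficient order for the variant (intercept first)."""
        return _design_from_parts(
            self.frame["y_rev"].to_numpy(float),
            self.frame["g"].to_numpy(float),
            self.variant,
        )

    def response(self) -> np.ndarray:
        return self.frame["y"].to_numpy(float)


@dataclass(frozen=True)
class FitResult:
    """OLS estimates for one variant at one round.

    ``estimates`` maps coefficient name -> value; ``r_squared`` is NaN with
    ``degenerate`` set when the response has zero variance; rank-deficient
    designs are solved by the minimal-norm pseudo-solution and flagged.
    """

    variant: str
    t: int
    estimates: dict[str, float]
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    rank_deficient: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class CoefficientTrajectory:
    """Per-round estimates and R^2 for one variant over a set of rounds."""

    variant: str
    rounds: np.ndarray
    estimates: dict[str, np.ndarray]   # term -> vector over rounds
    r_squared: np.ndarray
    rank_deficient: np.ndarray         # bool per round
    degenerate: np.ndarray             # bool per round

    def coefficient(self, term: str) -> np.ndarray:
        return self.estimates[term]

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.rounds, "r2": self.r_squared}
        cols.update(self.estimates)
        return pd.DataFrame(cols)


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """0-based (receiver, giver) index arrays over ordered pairs i != j."""
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    keep = i != j
    return i[keep], j[keep]


def _design_from_parts(y_rev: np.ndarray, g: np.ndarray, variant: str) -> np.ndarray:
    variant = _canon(variant)
    ones = np.ones_like(y_rev)
    cols = {"alpha": ones, "rho": y_rev, "gamma": g, "delta": g * y_rev}
    return np.column_stack([cols[term] for term in VARIANTS[variant]])


def build_design(game: GameData, t: int, variant: str = "additive") -> DyadicDataset:
    """Ordered-pair design table at round ``t`` for a two-group game."""
    variant = _canon(variant)
    if t < 1:
        raise GameValidationError("round out of range: design needs t >= 1")
    if len(game.groups.group_names) != 2:
        raise GameValidationError("group coding undefined: exactly two groups required")
    Y = cumulative_matrix(game, t).Y
    ii, jj = _pair_index(game.n_players)
    codes = game.groups.codes()
    frame = pd.DataFrame({
        "i": ii + 1,
        "j": jj + 1,
        "y": Y[ii, jj],
        "y_rev": Y[jj, ii],
        "g": (codes[ii] != codes[jj]).astype(int),
    })
    return DyadicDataset(t=t, variant=variant, frame=frame)


def _solve_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return beta, rank < X.shape[1]


def fit_ols(data: DyadicDataset) -> FitResult:
    """Ordinary least squares on one dyadic dataset.

    R^2 = 1 - SSR/SST with SST about the response mean; a zero-variance
    response yields NaN R^2 with the ``degenerate`` flag rather than an
    error, so trajectory sweeps survive trivial early rounds.
    """
    X = data.design_matrix()
    y = data.response()
    if len(y) < 2:
        raise GameValidationError("need at least two rows to fit")
    beta, rank_def = _solve_ols(X, y)
    fitted = X @ beta
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum(resid ** 2))
    degenerate = sst == 0.0
    r2 = float("nan") if degenerate else 1.0 - ssr / sst
    terms = VARIANTS[_canon(data.variant)]
    return FitResult(
        variant=_canon(data.variant), t=data.t,
        estimates={term: float(b) for term, b in zip(terms, beta)},
        r_squared=r2, residuals=resid,
        rank_deficient=rank_def, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Batched trajectory fitting. The per-round designs share the pair index and
# group dummy; only the cumulative counts change, so all rounds are fitted
# with one stacked normal-equations solve (minimal-norm lstsq fallback for
# singular rounds).

def _traj_from_cum(cum: np.ndarray, codes: np.ndarray, variant: str,
                   rounds: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Estimates (R x p), r2, rank flags and degenerate flags for the given rounds."""
    variant = _canon(variant)
    terms = VARIANTS[variant]
    p = len(terms)
    n = cum.shape[1]
    ii, jj = _pair_index(n)
    g = (codes[ii] != codes[jj]).astype(float)

    sel = cum[rounds - 1]                      # (R, n, n)
    y = sel[:, ii, jj].astype(float)           # (R, P)
    y_rev = sel[:, jj, ii].astype(float)
    R, P = y.shape

    X = np.empty((R, P, p))
    col = {"alpha": np.ones((R, P)), "rho": y_rev,
           "gamma": np.broadcast_to(g, (R, P)), "delta": g[None, :] * y_rev}
    for k, term in enumerate(terms):
        X[:, :, k] = col[term]

    XtX = np.einsum("rpk,rpl->rkl", X, X)
    Xty = np.einsum("rpk,rp->rk", X, y)
    rank_def = np.array([np.linalg.matrix_rank(XtX[r], hermitian=True) < p
                         for r in range(R)])
    beta = np.empty((R, p))
    ok = ~rank_def
    if ok.any():
        beta[ok] = np.linalg.solve(XtX[ok], Xty[ok][..., None])[..., 0]
    for r in np.flatnonzero(rank_def):
        beta[r], _ = _solve_ols(X[r], y[r])

    fitted = np.einsum("rpk,rk->rp", X, beta)
    ssr = np.sum((y - fitted) ** 2, axis=1)
    sst = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    degenerate = sst == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(degenerate, np.nan, 1.0 - ssr / np.where(degenerate, 1.0, sst))
    return beta, r2, rank_def, degenerate


def fit_trajectory(game: GameData, variant: str = "additive",
                   rounds: Sequence[int] | None = None) -> CoefficientTrajectory:
    """Fit one variant at each requested round (default: every round).

    Deterministic given the game; degenerate or rank-deficient rounds are
    flagged, never fatal.
    """
    variant = _canon(variant)
    if len(game.groups.group_names) != 2:
        raise GameValidationError("group coding undefined: exactly two groups required")
    rounds_arr = (np.arange(1, game.n_rounds + 1) if rounds is None
                  else np.asarray(sorted(int(t) for t in rounds)))
    if rounds_arr.size and (rounds_arr.min() < 1 or rounds_arr.max() > game.n_rounds):
        raise GameValidationError("round out of range in trajectory request")
    cum = cumulative_stack(game)
    beta, r2, rank_def, degenerate = _traj_from_cum(
        cum, game.groups.codes(), variant, rounds_arr)
    terms = VARIANTS[variant]
    return CoefficientTrajectory(
        variant=variant, rounds=rounds_arr,
        estimates={term: beta[:, k].copy() for k, term in enumerate(terms)},
        r_squared=r2, rank_deficient=rank_def, degenerate=degenerate,
    )
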