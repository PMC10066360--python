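"""Dyadic OLS: design construction, fits against independent oracles,
trajectories, nesting and invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tokengame import (
    GameConfig,
    GameData,
    GameValidationError,
    GroupAssignment,
    VARIANTS,
    build_design,
    fit_ols,
    fit_trajectory,
    toy4_game,
)
from tokengame.regression import DyadicDataset

from conftest import random_small_game


def normal_equations_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent least-squares solve via the pseudo-inverse (minimal norm)."""
    return np.linalg.pinv(X) @ y


class TestBuildDesign:
    def test_toy4_rows(self, toy4):
        data = build_design(toy4, 3, "interaction")
        assert data.n_rows == 12
        frame = data.frame.set_index(["i", "j"])
        assert tuple(frame.loc[(1, 3), ["y", "y_rev", "g"]]) == (3, 1, 1)
        assert tuple(frame.loc[(3, 4), ["y", "y_rev", "g"]]) == (2, 0, 0)

    def test_study_config_has_182_rows(self, null_game):
        for t in (1, 40):
            assert build_design(null_game, t).n_rows == 14 * 13

    def test_round1_responses_binary(self, null_game):
        assert set(build_design(null_game, 1).frame["y"].unique()) <= {0, 1}

    def test_more_than_two_groups_rejected(self):
        config = GameConfig(6, (2, 2, 2), 1, 5)
        groups = GroupAssignment(("A", "A", "B", "B", "C", "C"))
        game = GameData(config, groups, np.zeros((1, 6), dtype=int))
        with pytest.raises(GameValidationError, match="group coding undefined"):
            build_design(game, 1)

    def test_g_is_symmetric(self, null_game):
        frame = build_design(null_game, 40).frame
        g = frame.set_index(["i", "j"])["g"]
        for (i, j), val in g.items():
            assert g[(j, i)] == val


class TestFitOls:
    def test_toy4_group_only_equals_group_means(self, toy4):
        fit = fit_ols(build_design(toy4, 3, "group"))
        assert fit.estimates["alpha"] == pytest.approx(1.5, abs=1e-12)
        assert fit.estimates["gamma"] == pytest.approx(-1.0, abs=1e-12)

    def test_toy4_reciprocity_only_closed_form(self, toy4):
        fit = fit_ols(build_design(toy4, 3, "reciprocity"))
        assert fit.estimates["rho"] == pytest.approx(17 / 41, abs=1e-12)
        assert fit.estimates["alpha"] == pytest.approx(20 / 41, abs=1e-12)

    def test_perfectly_symmetric_game_gives_rho_one(self):
        config = GameConfig(4, (2, 2), 2, 5)
        groups = GroupAssignment.default_two_groups(config)
        rows = [(1, 1, 2), (1, 2, 1), (1, 3, 4), (1, 4, 3),
                (2, 1, 2), (2, 2, 1), (2, 3, 4), (2, 4, 3)]
        game = GameData.from_records(config, groups, rows)
        fit = fit_ols(build_design(game, 2, "reciprocity"))
        assert fit.estimates["rho"] == pytest.approx(1.0)
        assert fit.estimates["alpha"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_residuals_sum_to_zero_with_intercept(self, null_game):
        for variant in VARIANTS:
            fit = fit_ols(build_design(null_game, 40, variant))
            assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_response_flagged(self):
        config = GameConfig(4, (2, 2), 1, 5)
        groups = GroupAssignment.default_two_groups(config)
        rows = [(1, 1, 1), (1, 2, 2), (1, 3, 3), (1, 4, 4)]
        game = GameData.from_records(config, groups, rows)
        fit = fit_ols(build_design(game, 1, "additive"))
        assert fit.degenerate and np.isnan(fit.r_squared)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        game = random_small_game(seed)
        if game.n_rounds == 0:
            return
        for variant in VARIANTS:
            data = build_design(game, game.n_rounds, variant)
            fit = fit_ols(data)
            oracle = normal_equations_oracle(data.design_matrix(), data.response())
            assert np.allclose(list(fit.estimates.values()), oracle, atol=1e-10)

    def test_matches_statsmodels_on_study_game(self, null_game):
        import statsmodels.api as sm
        data = build_design(null_game, 40, "interaction")
        fit = fit_ols(data)
        res = sm.OLS(data.response(), data.design_matrix()).fit()
        assert np.allclose(list(fit.estimates.values()), res.params, atol=1e-10)
        assert fit.r_squared == pytest.approx(res.rsquared, abs=1e-10)

    def test_row_permutation_leaves_estimates_unchanged(self, null_game):
        data = build_design(null_game, 40, "additive")
        gen = np.random.default_rng(0)
        shuffled = DyadicDataset(
            t=data.t, variant=data.variant,
            frame=data.frame.sample(frac=1.0, random_state=gen).reset_index(drop=True))
        a = fit_ols(data).estimates
        b = fit_ols(shuffled).estimates
        assert np.allclose(list(a.values()), list(b.values()), atol=1e-10)


class TestTrajectory:
    def test_single_round_matches_fit_ols(self, toy4):
        traj = fit_trajectory(toy4, "reciprocity", rounds=[3])
        single = fit_ols(build_design(toy4, 3, "reciprocity"))
        assert traj.estimates["rho"][0] == pytest.approx(single.estimates["rho"], abs=1e-10)
        assert traj.r_squared[0] == pytest.approx(single.r_squared, abs=1e-10)

    def test_all_rounds_match_per_round_fits(self, null_game):
        traj = fit_trajectory(null_game, "additive")
        for t in (1, 10, 40):
            single = fit_ols(build_design(null_game, t, "additive"))
            idx = t - 1
            for term, value in single.estimates.items():
                assert traj.estimates[term][idx] == pytest.approx(value, abs=1e-9)

    def test_constant_game_has_constant_coefficients(self):
        # same allocations every round: Y scales linearly with t, so the
        # regression surface is invariant up to that scaling
        config = GameConfig(4, (2, 2), 6, 10)
        groups = GroupAssignment.default_two_groups(config)
        rows = [(t, 1, 2) for t in range(1, 7)] + [(t, 2, 1) for t in range(1, 7)] \
             + [(t, 3, 1) for t in range(1, 7)] + [(t, 4, 3) for t in range(1, 7)]
        game = GameData.from_records(config, groups, rows)
        traj = fit_trajectory(game, "group")
        gamma = traj.estimates["gamma"]
        assert np.allclose(gamma / np.arange(1, 7), gamma[0], atol=1e-10)

    def test_group_relabelling_invariance(self, null_game):
        swapped = GameData(
            null_game.config,
            GroupAssignment(tuple("B" if lab == "A" else "A"
                                  for lab in null_game.groups.labels)),
            null_game.receivers,
        )
        a = fit_trajectory(null_game, "additive")
        b = fit_trajectory(swapped, "additive")
        for term in a.estimates:
            assert np.allclose(a.estimates[term], b.estimates[term], atol=1e-10)

    def test_null_game_gamma_fluctuates_around_zero(self, null_game):
        gamma = fit_trajectory(null_game, "additive").estimates["gamma"]
        assert abs(np.nanmean(gamma)) < 0.5

    def test_round_out_of_range(self, toy4):
        with pytest.raises(GameValidationError, match="round out of range"):
            fit_trajectory(toy4, "additive", rounds=[5])


class TestNesting:
    @pytest.mark.parametrize("fixture_name", ["toy4", "null", "locked", "biased"])
    def test_r2_nesting(self, fixture_name, toy4):
        from tokengame import ingroup_biased_game, locked_pair_game, null_fixture_game
        game = {
            "toy4": toy4,
            "null": null_fixture_game(3),
            "locked": locked_pair_game(3),
            "biased": ingroup_biased_game(3),
        }[fixture_name]
        r2 = {v: fit_trajectory(game, v).r_squared for v in VARIANTS}
        for t_idx in range(game.n_rounds):
            vals = {v: r2[v][t_idx] for v in VARIANTS}
            if any(np.isnan(x) for x in vals.values()):
                continue
            eps = 1e-10
            assert vals["additive"] >= max(vals["reciprocity"], vals["group"]) - eps
            assert vals["interaction"] >= vals["additive"] - eps
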