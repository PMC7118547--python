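"""Regression, model grid, median splits, and ANCOVA contracts."""

import numpy as np
import pandas as pd
import pytest

from oracles import ancova_reference, ols_reference
from sedpatterns import (
    ModelSpec,
    assign_groups,
    fit_ancova,
    fit_linear_model,
    run_model_grid,
)
from sedpatterns.errors import (
    CollinearityError,
    InsufficientDataError,
    ValidationError,
)
from sedpatterns.models import GROUP_LEVELS, MODEL_FAMILIES


def _random_dataset(rng, n=80, n_cov=3):
    df = pd.DataFrame(
        rng.normal(size=(n, n_cov + 1)), columns=["x"] + [f"c{i}" for i in range(n_cov)]
    )
    beta = rng.normal(size=n_cov + 1)
    df["y"] = 1.0 + df.to_numpy() @ beta + rng.normal(0, 2, n)
    return df


class TestLinearModel:
    def test_exact_recovery_noise_free(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = 2.0 * df["x"] + 3.0
        r = fit_linear_model(df, ModelSpec("y", "x", covariates=()))
        assert r.B == pytest.approx(2.0, abs=1e-10)
        assert r.p < 1e-12
        assert r.beta > 0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            df = _random_dataset(rng)
            covs = tuple(c for c in df.columns if c.startswith("c"))
            r = fit_linear_model(df, ModelSpec("y", "x", covariates=covs))
            coef, se, p, lo, hi = ols_reference(
                df["y"].to_numpy(), df[["x", *covs]].to_numpy()
            )
            assert r.B == pytest.approx(coef[1], abs=1e-8)
            assert r.SE == pytest.approx(se[1], abs=1e-8)
            assert r.p == pytest.approx(p[1], abs=1e-8)
            assert r.ci95[0] == pytest.approx(lo[1], abs=1e-8)
            assert r.ci95[1] == pytest.approx(hi[1], abs=1e-8)
            beta_oracle = coef[1] * df["x"].std(ddof=1) / df["y"].std(ddof=1)
            assert r.beta == pytest.approx(beta_oracle, abs=1e-10)

    def test_affine_rescaling_of_covariates_leaves_exposure_unchanged(self):
        rng = np.random.default_rng(13)
        df = _random_dataset(rng)
        covs = ("c0", "c1", "c2")
        r1 = fit_linear_model(df, ModelSpec("y", "x", covariates=covs))
        df2 = df.copy()
        df2["c0"] = 100 * df2["c0"] - 7
        df2["c1"] = df2["c1"] / 3 + 2
        r2 = fit_linear_model(df2, ModelSpec("y", "x", covariates=covs))
        assert r2.B == pytest.approx(r1.B, rel=1e-10)
        assert r2.beta == pytest.approx(r1.beta, rel=1e-10)
        assert r2.p == pytest.approx(r1.p, rel=1e-8)

    def test_beta_invariant_under_exposure_outcome_rescaling(self):
        rng = np.random.default_rng(17)
        df = _random_dataset(rng)
        r1 = fit_linear_model(df, ModelSpec("y", "x", covariates=("c0",)))
        df2 = df.assign(x=df["x"] * 10, y=df["y"] / 5)
        r2 = fit_linear_model(df2, ModelSpec("y", "x", covariates=("c0",)))
        assert r2.beta == pytest.approx(r1.beta, rel=1e-10)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(19)
        df = _random_dataset(rng)
        df["c_dup"] = 2 * df["c0"]
        with pytest.raises(CollinearityError, match="c"):
            fit_linear_model(df, ModelSpec("y", "x", covariates=("c0", "c_dup")))

    def test_insufficient_data_error(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [1.0, 2.0, 1.5], "c0": [0.0, 1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            fit_linear_model(df, ModelSpec("y", "x", covariates=("c0",)))

    def test_listwise_deletion(self):
        rng = np.random.default_rng(23)
        df = _random_dataset(rng, n=60)
        df.loc[:9, "c0"] = np.nan
        r = fit_linear_model(df, ModelSpec("y", "x", covariates=("c0",)))
        assert r.n == 50


class TestModelGrid:
    def test_cardinality(self):
        rng = np.random.default_rng(29)
        df = _random_dataset(rng)
        df["x2"] = rng.normal(size=len(df))
        grid = run_model_grid(
            df.assign(**{c: rng.normal(size=len(df)) for c in MODEL_FAMILIES["base"]}),
            outcomes=["y"],
            exposures=["x", "x2"],
            families=["base", "base_mvpa"],
        )
        assert len(grid) == 1 * 2 * 2
        assert grid.attrs["n_tests"] == 4

    def test_degenerate_cell_flagged_rest_intact(self):
        rng = np.random.default_rng(31)
        n = 80
        df = pd.DataFrame({c: rng.normal(size=n) for c in MODEL_FAMILIES["base"]})
        df["y"] = rng.normal(size=n)
        df["x_ok"] = rng.normal(size=n)
        df["x_const"] = 1.0  # collinear with the intercept
        grid = run_model_grid(df, ["y"], ["x_ok", "x_const"], ["base"])
        ok = grid[grid["exposure"] == "x_ok"].iloc[0]
        bad = grid[grid["exposure"] == "x_const"].iloc[0]
        assert ok["error"] == "" and np.isfinite(ok["B"])
        assert bad["error"] != "" and np.isnan(bad["B"])


class TestGroupAssignment:
    def _table(self, st_vals, dur_vals):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(len(st_vals))],
                "st_minutes_per_week": st_vals,
                "mean_bout_duration_30": dur_vals,
            }
        )

    def test_median_split_four_values(self):
        g = assign_groups(self._table([1, 2, 3, 4], [1, 2, 3, 4]))
        assert list(g["st_group"]) == ["low", "low", "high", "high"]

    def test_tie_at_median_goes_low(self):
        g = assign_groups(self._table([1, 2, 2, 4, 5], [1, 1, 1, 1, 1]))
        # median is 2; both 2s are "low"
        assert list(g["st_group"]) == ["low", "low", "low", "high", "high"]

    def test_no_prolonged_bout_policies(self):
        t = self._table([1, 2, 3, 4], [np.nan, 40, 50, 60])
        g_zero = assign_groups(t, zero_bout_policy="zero")
        assert len(g_zero) == 4 and g_zero.attrs["n_zero_bout"] == 1
        assert g_zero["bout_group"].iloc[0] == "low"
        g_ex = assign_groups(t, zero_bout_policy="exclude")
        assert len(g_ex) == 3
        with pytest.raises(ValidationError):
            assign_groups(t, zero_bout_policy="drop")

    def test_group_sizes_match_exhaustive_reassignment(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            st_vals = rng.normal(3000, 500, n)
            dur = rng.normal(48, 10, n)
            g = assign_groups(self._table(st_vals, dur))
            st_med, dur_med = np.median(st_vals), np.median(dur)
            for i in range(n):
                expect = ("low" if st_vals[i] <= st_med else "high") + "_" + (
                    "low" if dur[i] <= dur_med else "high"
                )
                assert g["joint_group"].iloc[i] == expect


def _ancova_data(rng, n=200, effect=0.0, covariate_slopes=(1.5, -2.0)):
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "st_minutes_per_week": rng.normal(3216, 600, n),
            "mean_bout_duration_30": rng.normal(48, 10, n),
            "cov_a": rng.normal(size=n),
            "cov_b": rng.normal(size=n),
        }
    )
    groups = assign_groups(df)
    joint = df["participant_id"].map(
        groups.set_index("participant_id")["joint_group"]
    )
    df["y"] = (
        50
        + covariate_slopes[0] * df["cov_a"]
        + covariate_slopes[1] * df["cov_b"]
        + effect * (joint == "high_high")
        + rng.normal(0, 5, n)
    )
    df.attrs["joint"] = joint
    return df, groups


class TestAncova:
    def test_covariate_free_adjusted_means_equal_raw_means(self):
        rng = np.random.default_rng(41)
        df, groups = _ancova_data(rng, covariate_slopes=(0, 0))
        res = fit_ancova(df, groups, "y", covariates=())
        for g in GROUP_LEVELS:
            raw = df.loc[(df.attrs["joint"] == g).to_numpy(), "y"].mean()
            assert res.adjusted_means[g] == pytest.approx(raw, abs=1e-10)

    def test_matches_group_mean_centering_oracle(self):
        rng = np.random.default_rng(43)
        df, groups = _ancova_data(rng)
        res = fit_ancova(df, groups, "y", covariates=("cov_a", "cov_b"))
        joint = df.attrs["joint"].to_numpy()
        means, _ = ancova_reference(
            df["y"].to_numpy(),
            df[["cov_a", "cov_b"]].to_numpy(),
            joint,
            GROUP_LEVELS,
        )
        for g in GROUP_LEVELS:
            assert res.adjusted_means[g] == pytest.approx(means[g], abs=1e-8)
        # contrasts equal differences of oracle means; SE/p via normal equations
        dummies = np.column_stack(
            [(joint == g).astype(float) for g in GROUP_LEVELS[1:]]
        )
        X = np.column_stack([dummies, df[["cov_a", "cov_b"]].to_numpy()])
        coef, se, p, _, _ = ols_reference(df["y"].to_numpy(), X)
        row = res.contrasts.set_index(["group1", "group2"])
        got = row.loc[("low_low", "high_high")]
        assert got["diff"] == pytest.approx(-coef[3], abs=1e-8)
        assert got["se"] == pytest.approx(se[3], abs=1e-8)
        assert got["p"] == pytest.approx(p[3], abs=1e-8)

    def test_six_pairwise_contrasts(self):
        rng = np.random.default_rng(47)
        df, groups = _ancova_data(rng)
        res = fit_ancova(df, groups, "y", covariates=("cov_a", "cov_b"))
        assert len(res.contrasts) == 6

    def test_empty_group_lists_sizes(self):
        rng = np.random.default_rng(53)
        df, groups = _ancova_data(rng, n=40)
        df = df[(df.attrs["joint"] != "low_high").to_numpy()]
        with pytest.raises(InsufficientDataError, match="low_high"):
            fit_ancova(df, groups, "y", covariates=("cov_a",))

    def test_known_group_effect_estimated(self):
        rng = np.random.default_rng(59)
        df, groups = _ancova_data(rng, n=400, effect=-8.0)
        res = fit_ancova(df, groups, "y", covariates=("cov_a", "cov_b"))
        row = res.contrasts.set_index(["group1", "group2"]).loc[("low_low", "high_high")]
        assert row["diff"] == pytest.approx(8.0, abs=2.0)
        assert row["ci_low"] <= 8.0 <= row["ci_high"]

    def test_mvpa_adjustment_with_null_mvpa_effect_is_stable(self):
        rng = np.random.default_rng(61)
        df, groups = _ancova_data(rng, n=400, effect=-6.0)
        df["mvpa_minutes_per_day"] = rng.normal(44, 30, len(df))
        r0 = fit_ancova(df, groups, "y", covariates=("cov_a", "cov_b"))
        r1 = fit_ancova(
            df, groups, "y", covariates=("cov_a", "cov_b"), include_mvpa=True
        )
        d0 = r0.contrasts.set_index(["group1", "group2"]).loc[("low_low", "high_high"), "diff"]
        d1 = r1.contrasts.set_index(["group1", "group2"]).loc[("low_low", "high_high"), "diff"]
        assert d1 == pytest.approx(d0, abs=1.0)
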