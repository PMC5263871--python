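"""Variance imputation, heterogeneity, and the three-level REML model."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from recoverydebt.meta import (
    ThreeLevelMetaAnalysis,
    category_estimates,
    compare_subcategories,
    fit_three_level,
    i_squared,
    impute_variances,
    omnibus_test,
)

from helpers import golden_two_level, grid_reml


def _effects_frame(y, v, study, **extra):
    return pd.DataFrame({"effect": y, "variance": v, "study_id": study, **extra})


def _simulate(rng, n_studies, effects_per_study, mu=40.0, tau2_study=10.0,
              tau2_effect=5.0, v=1.0, moderator_levels=None, deltas=None):
    npr = rng.integers(*effects_per_study, n_studies)
    n = int(npr.sum())
    study = np.repeat([f"S{j}" for j in range(n_studies)], npr)
    y = (mu + np.repeat(rng.normal(0, np.sqrt(tau2_study), n_studies), npr)
         + rng.normal(0, np.sqrt(tau2_effect), n)
         + rng.normal(0, np.sqrt(v), n))
    df = _effects_frame(y, np.full(n, float(v)), study)
    if moderator_levels is not None:
        lab = rng.choice(moderator_levels, n)
        if deltas:
            y = df["effect"].to_numpy() + np.array([deltas[l] for l in lab])
            df["effect"] = y
        df["mod"] = lab
    return df


class TestImputation:
    def test_group_mean_fills_missing(self):
        df = pd.DataFrame(
            {"metric": ["a"] * 3, "variance": [2.0, 4.0, None], "effect": [1, 2, 3]}
        )
        out = impute_variances(df)
        assert out["variance"].tolist() == [2.0, 4.0, 3.0]
        assert out["imputed"].tolist() == [False, False, True]

    def test_fully_observed_untouched(self):
        df = pd.DataFrame({"metric": ["a", "a"], "variance": [1.0, 2.0]})
        out = impute_variances(df)
        assert out["variance"].tolist() == [1.0, 2.0] and not out["imputed"].any()

    def test_unobserved_group_raises_naming_it(self):
        df = pd.DataFrame({"metric": ["a", "b"], "variance": [1.0, None]})
        with pytest.raises(ValueError, match="'b'"):
            impute_variances(df)

    def test_heavy_masking_still_yields_positive_variances(self):
        rng = np.random.default_rng(0)
        n = 500
        v = rng.lognormal(1, 0.5, n)
        mask = rng.uniform(size=n) < 0.79
        df = pd.DataFrame(
            {"metric": rng.choice(["a", "d"], n), "variance": np.where(mask, np.nan, v)}
        )
        out = impute_variances(df)
        assert (out["variance"] > 0).all()
        assert out["imputed"].mean() == pytest.approx(0.79, abs=0.06)


class TestISquared:
    def test_identical_effects_give_zero(self):
        assert i_squared([3.0, 3.0, 3.0], [1.0, 2.0, 1.0]) == 0.0

    def test_hand_computed_example(self):
        # w = {1,1}, weighted mean 1, Q = 2, I^2 = (2-1)/2 = 50%
        assert i_squared([0.0, 2.0], [1.0, 1.0]) == pytest.approx(50.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10, 3, 20)
        v = rng.lognormal(0, 0.5, 20)
        base = i_squared(y, v)
        ybar = np.sum(y / v) / np.sum(1 / v)
        scaled = i_squared(ybar + 3.0 * (y - ybar), 9.0 * v)
        assert scaled == pytest.approx(base, rel=1e-10)

    def test_dominant_heterogeneity_pushes_i2_above_90(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(100):
            v = np.full(40, 1.0)
            y = rng.normal(40, np.sqrt(30.0), 40) + rng.normal(0, 1, 40)
            vals.append(i_squared(y, v))
        # heuristic: I^2 ~ tau2/(tau2+v) = 30/31 ~ 97%
        assert np.mean(vals) > 90.0

    def test_needs_two_effects(self):
        with pytest.raises(ValueError):
            i_squared([1.0], [1.0])


class TestThreeLevelFit:
    def test_single_study_single_effect(self):
        fit = fit_three_level(_effects_frame([12.0], [4.0], ["S1"]))
        assert fit.mu == pytest.approx(12.0)
        assert fit.se == pytest.approx(2.0)
        assert fit.tau2_study == 0.0 and fit.tau2_effect == 0.0

    def test_zero_heterogeneity_data(self):
        df = _effects_frame([7.0] * 10, [1.0] * 10, [f"S{i // 2}" for i in range(10)])
        fit = fit_three_level(df)
        assert fit.mu == pytest.approx(7.0)
        assert fit.tau2_study == pytest.approx(0.0, abs=1e-8)
        assert fit.tau2_effect == pytest.approx(0.0, abs=1e-8)

    def test_weighted_mean_limit(self):
        rng = np.random.default_rng(3)
        y = rng.normal(30, 2, 12)
        df = _effects_frame(y, [2.5] * 12, [f"S{i}" for i in range(12)])
        fit = fit_three_level(df, fix_tau2_study=0.0, fix_tau2_effect=0.0)
        assert fit.mu == pytest.approx(float(np.mean(y)), rel=1e-10)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(8):
            df = _simulate(rng, 5, (2, 4), tau2_study=25.0, tau2_effect=4.0)
            fit = fit_three_level(df)
            ll_grid, ts, te, res = grid_reml(
                df["effect"], df["variance"], df["study_id"]
            )
            assert fit.loglik_reml >= ll_grid - 1e-6
            assert abs(fit.tau2_study - ts) <= max(4 * res, 0.05)
            assert abs(fit.tau2_effect - te) <= max(4 * res, 0.05)

    def test_two_level_equivalence(self):
        """One effect per study with the between-study component pinned at 0
        reproduces the standard random-effects meta-analysis."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(5, 12))
            v = rng.lognormal(0, 0.4, k)
            y = rng.normal(35, 4, k) + rng.normal(0, np.sqrt(v))
            df = _effects_frame(y, v, [f"S{i}" for i in range(k)])
            fit = fit_three_level(df, fix_tau2_study=0.0)
            t2, mu = golden_two_level(y, v)
            assert fit.mu == pytest.approx(mu, abs=1e-6)
            assert fit.tau2_effect == pytest.approx(t2, abs=1e-5)

    def test_matches_metafor_reference(self, tmp_path):
        """Independent cross-check against R's rma.mv on a small dataset."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the metafor cross-check")
        rng = np.random.default_rng(42)
        df = _simulate(rng, 5, (2, 3), tau2_study=25.0, tau2_effect=4.0)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(metafor))
            d <- read.csv('{csv}')
            d$effect_id <- seq_len(nrow(d))
            f <- rma.mv(effect, variance, random = ~ 1 | study_id/effect_id,
                        data = d, method = "REML")
            cat(sprintf("%.10f %.10f %.10f %.10f %.10f\\n",
                coef(f), f$se, f$sigma2[1], f$sigma2[2], logLik(f)))
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        mu, se, ts, te, ll = map(float, out.stdout.split())
        fit = fit_three_level(df)
        assert fit.mu == pytest.approx(mu, abs=1e-4)
        assert fit.se == pytest.approx(se, abs=1e-4)
        assert fit.tau2_study == pytest.approx(ts, abs=1e-2)
        assert fit.tau2_effect == pytest.approx(te, abs=1e-2)
        assert fit.loglik_reml == pytest.approx(ll, abs=1e-4)

    def test_rejects_nonpositive_variances(self):
        with pytest.raises(ValueError, match="variance"):
            fit_three_level(_effects_frame([1.0, 2.0], [1.0, 0.0], ["a", "b"]))

    def test_estimator_params_roundtrip(self):
        est = ThreeLevelMetaAnalysis(moderator="eco", intercept=False)
        clone = ThreeLevelMetaAnalysis(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestModerators:
    def test_omnibus_df_is_categories_minus_one(self):
        rng = np.random.default_rng(6)
        df = _simulate(rng, 30, (2, 4), moderator_levels=["x", "y", "z"])
        fit = fit_three_level(df, moderator="mod", intercept=True)
        q, dof, p = omnibus_test(fit)
        assert dof == 2 and q >= 0 and 0 <= p <= 1

    def test_omnibus_requires_moderator(self):
        fit = fit_three_level(_effects_frame([1.0, 2.0], [1.0, 1.0], ["a", "b"]))
        with pytest.raises(ValueError):
            omnibus_test(fit)

    def test_omnibus_power_for_large_shift(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            df = _simulate(rng, 20, (2, 3), tau2_study=1.0, tau2_effect=0.5,
                           moderator_levels=["x", "y"], deltas={"x": 0.0, "y": 30.0})
            fit = fit_three_level(df, moderator="mod", intercept=True)
            assert fit.q_m_p < 0.001

    def test_single_category_equals_pooled_fit(self):
        rng = np.random.default_rng(8)
        df = _simulate(rng, 10, (2, 3))
        df["mod"] = "only"
        cell = fit_three_level(df, moderator="mod", intercept=False)
        pooled = fit_three_level(df)
        row = category_estimates(cell).iloc[0]
        assert row["mean"] == pytest.approx(pooled.mu, abs=1e-6)
        assert row["ci_low"] == pytest.approx(pooled.ci_low, abs=1e-5)
        assert row["n_studies"] == pooled.n_studies

    def test_category_estimates_requires_no_intercept(self):
        rng = np.random.default_rng(9)
        df = _simulate(rng, 20, (2, 3), moderator_levels=["x", "y"])
        fit = fit_three_level(df, moderator="mod", intercept=True)
        with pytest.raises(ValueError):
            category_estimates(fit)

    def test_category_ci_covers_truth(self):
        rng = np.random.default_rng(10)
        truth = {"x": 30.0, "y": 45.0, "z": 60.0}
        cover = {c: 0 for c in truth}
        n_sims = 40
        for _ in range(n_sims):
            df = _simulate(rng, 40, (2, 4), mu=0.0, moderator_levels=list(truth),
                           deltas=truth)
            fit = fit_three_level(df, moderator="mod", intercept=False)
            for _, row in fit.category_estimates.iterrows():
                if row["ci_low"] <= truth[row["label"]] <= row["ci_high"]:
                    cover[row["label"]] += 1
        for c, n_cov in cover.items():
            assert n_cov / n_sims >= 0.85

    def test_small_category_rejected_with_clear_error(self):
        df = _effects_frame([1, 2, 3], [1, 1, 1], ["a", "a", "b"],
                            mod=["x", "x", "y"])
        with pytest.raises(ValueError, match="categories with < 2"):
            fit_three_level(df, moderator="mod", intercept=True)


class TestSubcategories:
    @staticmethod
    def _sub_frame(rng, n_per_side=50, shift=0.0):
        y1 = rng.normal(40, 8, n_per_side)
        y2 = rng.normal(40 + shift, 8, n_per_side)
        return pd.DataFrame(
            {
                "effect": np.concatenate([y1, y2]),
                "variance": np.ones(2 * n_per_side),
                "study_id": [f"S{i // 2}" for i in range(2 * n_per_side)],
                "submetric": ["richness"] * n_per_side + ["diversity_index"] * n_per_side,
            }
        )

    def test_identical_distributions_mostly_nonsignificant(self):
        rng = np.random.default_rng(11)
        nonsig = sum(
            compare_subcategories(self._sub_frame(rng), ("richness", "diversity_index")).p_value > 0.1
            for _ in range(30)
        )
        assert nonsig / 30 >= 0.8

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            cmp = compare_subcategories(
                self._sub_frame(rng, shift=20.0), ("richness", "diversity_index")
            )
            assert cmp.p_value < 0.05
        assert set(cmp.fits) == {"richness", "diversity_index"}

    def test_empty_side_errors(self):
        rng = np.random.default_rng(13)
        df = self._sub_frame(rng)
        df = df[df["submetric"] == "richness"]
        with pytest.raises(ValueError, match="diversity_index"):
            compare_subcategories(df, ("richness", "diversity_index"))
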