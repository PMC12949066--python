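import numpy as np
import pandas as pd
import pytest

from peersync.models import (ModelSpec, build_fixed_design, fit_model, icc,
                             screen_covariates, select_structure,
                             variance_explained_by_level)


def _hierarchical_data(rng, n_groups=20, units_per_group=6, obs_per_unit=10,
                       sd_group=1.0, sd_unit=1.0, sd_res=1.0,
                       beta_mutual=0.0, beta_time=0.0, sd_slope=0.0,
                       phi=0.0, beta_closeness=0.0):
    """Direct generator for mixed-model recovery tests (no cardiac chain)."""
    rows = []
    for g in range(n_groups):
        gid = f"g{g}"
        ug = rng.normal(0, sd_group)
        for u in range(units_per_group):
            uid = f"{gid}d{u}"
            uu = rng.normal(0, sd_unit)
            mutual = rng.random() < 0.3
            closeness = rng.normal(5, 2) + 2.0 * mutual
            slope = rng.normal(0, sd_slope) if sd_slope else 0.0
            eps_prev = 0.0
            for t in range(obs_per_unit):
                e = rng.normal(0, sd_res)
                eps = phi * eps_prev + np.sqrt(1 - phi**2) * e if phi else e
                eps_prev = eps
                y = (ug + uu + beta_mutual * mutual + beta_time * t
                     + slope * t + beta_closeness * 0.0 + eps)
                rows.append({"y": y, "group_id": gid, "dyad_id": uid,
                             "time": float(t),
                             "friendship_status": "mutual" if mutual else "none",
                             "closeness": closeness, "phase": "story"})
    return pd.DataFrame(rows)


BASE_SPEC = ModelSpec(outcome="y", group_col="group_id", unit_col="dyad_id",
                      categorical={"friendship_status": "none"},
                      continuous=("closeness",), time_col="time")


class TestICC:
    def test_equal_components_fifty_percent(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in range(150):
            ug = rng.normal(0, 1.0)
            for _ in range(10):
                rows.append({"y": ug + rng.normal(0, 1.0), "g": f"g{g}"})
        out = icc(pd.DataFrame(rows), "y", "g")
        assert out["g"] == pytest.approx(50.0, abs=6.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.standard_normal(1500),
                           "g": np.repeat([f"g{i}" for i in range(150)], 10)})
        assert icc(df, "y", "g")["g"] < 5.0

    def test_known_components_recovered(self):
        """sigma_unit^2 = 3, sigma_res^2 = 1 -> ICC 75%, averaged over reps."""
        vals = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            rows = []
            for g in range(80):
                ug = rng.normal(0, np.sqrt(3.0))
                for _ in range(8):
                    rows.append({"y": ug + rng.normal(0, 1.0), "g": f"g{g}"})
            vals.append(icc(pd.DataFrame(rows), "y", "g")["g"])
        assert np.mean(vals) == pytest.approx(75.0, abs=5.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        df = _hierarchical_data(rng, n_groups=10, obs_per_unit=5)
        a = icc(df, "y", "group_id", "dyad_id")
        df2 = df.assign(y=df["y"] + 100.0)
        b = icc(df2, "y", "group_id", "dyad_id")
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-4)

    def test_zero_variance_errors(self):
        df = pd.DataFrame({"y": np.ones(20),
                           "g": np.repeat(["a", "b"], 10)})
        with pytest.raises(ValueError):
            icc(df, "y", "g")


class TestScreenCovariates:
    def test_identical_candidate_retained(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(100)
        df = pd.DataFrame({"y": y, "self": y})
        inc, log = screen_covariates(df, "y", {"self": "continuous"})
        assert inc == ["self"]

    def test_independent_candidate_excluded_mostly(self):
        excluded = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            df = pd.DataFrame({"y": rng.standard_normal(200),
                               "x": rng.standard_normal(200)})
            inc, _ = screen_covariates(df, "y", {"x": "continuous"})
            excluded += "x" not in inc
        assert excluded / reps >= 0.85  # alpha=.05 type-I behavior

    def test_only_associated_candidate_retained(self):
        hits, spurious = 0, 0
        for rep in range(10):
            rng = np.random.default_rng(50 + rep)
            x1 = rng.standard_normal(300)
            df = pd.DataFrame({
                "y": x1 * 0.8 + rng.standard_normal(300),
                "x1": x1,
                "x2": rng.standard_normal(300),
                "x3": rng.standard_normal(300),
            })
            inc, _ = screen_covariates(
                df, "y", {k: "continuous" for k in ("x1", "x2", "x3")})
            hits += "x1" in inc
            spurious += len([c for c in inc if c != "x1"])
        assert hits == 10
        assert spurious / 10 < 0.5

    def test_categorical_candidate_tested_by_anova(self):
        rng = np.random.default_rng(3)
        g = np.repeat(["a", "b", "c"], 100)
        y = rng.standard_normal(300) + (g == "a") * 1.5
        df = pd.DataFrame({"y": y, "grp": g})
        inc, log = screen_covariates(df, "y", {"grp": "categorical"})
        assert inc == ["grp"]
        assert log.iloc[0]["test"] == "anova_F"

    def test_constant_candidate_skipped(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"y": rng.standard_normal(50), "c": np.ones(50)})
        inc, log = screen_covariates(df, "y", {"c": "continuous"})
        assert inc == []
        assert "skipped" in log.iloc[0]["test"]


class TestFitModel:
    def test_planted_effect_recovered(self):
        """+0.24 mutual effect: mean estimate within ±0.1, significant often."""
        ests, sig = [], 0
        reps = 8
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            df = _hierarchical_data(rng, n_groups=25, units_per_group=8,
                                    obs_per_unit=12, sd_group=0.3, sd_unit=0.3,
                                    sd_res=0.8, beta_mutual=0.24)
            fit = fit_model(BASE_SPEC, df)
            row = fit.coef("friendship_status__mutual")
            ests.append(row["estimate"])
            sig += row["p"] < 0.05
        assert np.mean(ests) == pytest.approx(0.24, abs=0.1)
        assert sig / reps >= 0.8

    def test_null_effect_interval_coverage(self):
        covered = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            df = _hierarchical_data(rng, n_groups=20, units_per_group=6,
                                    obs_per_unit=10)
            fit = fit_model(BASE_SPEC, df)
            row = fit.coef("closeness")
            covered += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert covered / reps >= 0.8

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(5)
        df = _hierarchical_data(rng, n_groups=60, units_per_group=8,
                                obs_per_unit=10, sd_group=1.0, sd_unit=0.7,
                                sd_res=0.5)
        spec = ModelSpec(outcome="y", group_col="group_id", unit_col="dyad_id")
        fit = fit_model(spec, df)
        assert fit.variance_components["group_id"] == pytest.approx(1.0, rel=0.3)
        assert fit.variance_components["dyad_id"] == pytest.approx(0.49, rel=0.3)
        assert fit.resid_var == pytest.approx(0.25, rel=0.1)

    def test_rank_deficiency_names_aliased_column(self):
        rng = np.random.default_rng(6)
        df = _hierarchical_data(rng, n_groups=8, obs_per_unit=5)
        df["closeness2"] = df["closeness"] * 2.0
        spec = ModelSpec(outcome="y", group_col="group_id", unit_col="dyad_id",
                         continuous=("closeness", "closeness2"))
        with pytest.raises(ValueError, match="closeness2"):
            fit_model(spec, df)

    def test_ar1_phi_estimated(self):
        rng = np.random.default_rng(7)
        df = _hierarchical_data(rng, n_groups=20, units_per_group=6,
                                obs_per_unit=20, phi=0.5)
        spec = ModelSpec(outcome="y", group_col="group_id", unit_col="dyad_id",
                         ar1=True)
        fit = fit_model(spec, df)
        assert fit.ar1_phi == pytest.approx(0.5, abs=0.15)

    def test_dummy_reference_invariance(self):
        """Fixed-effect predictions do not depend on the reference level."""
        rng = np.random.default_rng(8)
        df = _hierarchical_data(rng, n_groups=12, obs_per_unit=6,
                                beta_mutual=0.5)
        preds = {}
        for ref in ("none", "mutual"):
            spec = ModelSpec(outcome="y", group_col="group_id",
                             unit_col="dyad_id",
                             categorical={"friendship_status": ref})
            fit = fit_model(spec, df)
            dfd, cols = build_fixed_design(df, spec)
            X = np.column_stack([np.ones(len(dfd))] +
                                [dfd[c].to_numpy(float) for c in cols])
            tab = fit.coefficients.set_index("term")
            beta = np.array([tab.loc["(Intercept)", "estimate"]] +
                            [tab.loc[c, "estimate"] for c in cols])
            preds[ref] = X @ beta
        np.testing.assert_allclose(preds["none"], preds["mutual"], atol=1e-4)


class TestMarginalR2:
    def test_null_fixed_structure_zero(self):
        rng = np.random.default_rng(9)
        df = _hierarchical_data(rng, n_groups=10, obs_per_unit=5)
        spec = ModelSpec(outcome="y", group_col="group_id", unit_col="dyad_id")
        fit = fit_model(spec, df)
        assert fit.marginal_r2 == pytest.approx(0.0, abs=1e-6)

    def test_strong_fixed_effect_near_one(self):
        rng = np.random.default_rng(10)
        df = _hierarchical_data(rng, n_groups=10, obs_per_unit=20,
                                sd_group=0.01, sd_unit=0.01, sd_res=0.01,
                                beta_time=1.0)
        spec = ModelSpec(outcome="y", group_col="group_id", unit_col="dyad_id",
                         time_col="time")
        fit = fit_model(spec, df)
        assert fit.marginal_r2 > 0.99

    def test_known_decomposition(self):
        rng = np.random.default_rng(11)
        # var(fixed) = beta^2 var(t); t uniform 0..9 -> var = 8.25
        df = _hierarchical_data(rng, n_groups=40, units_per_group=6,
                                obs_per_unit=10, sd_group=1.0, sd_unit=1.0,
                                sd_res=1.0, beta_time=0.5)
        spec = ModelSpec(outcome="y", group_col="group_id", unit_col="dyad_id",
                         time_col="time")
        fit = fit_model(spec, df)
        expected = (0.25 * 8.25) / (0.25 * 8.25 + 3.0)
        assert fit.marginal_r2 == pytest.approx(expected, rel=0.1)


class TestSelectStructure:
    def _spec(self):
        return ModelSpec(outcome="y", group_col="group_id",
                         unit_col="dyad_id", time_col="time")

    def test_no_ar1_step_rejected(self):
        rejected = 0
        reps = 12
        for rep in range(reps):
            rng = np.random.default_rng(400 + rep)
            df = _hierarchical_data(rng, n_groups=12, units_per_group=5,
                                    obs_per_unit=10, phi=0.0)
            _spec, log = select_structure(self._spec(), df)
            step = log[log["step"] == "ar1"]
            rejected += step.empty or not step.iloc[0]["accepted"]
        assert rejected / reps >= 0.8

    def test_strong_ar1_detected(self):
        rng = np.random.default_rng(500)
        df = _hierarchical_data(rng, n_groups=15, units_per_group=6,
                                obs_per_unit=25, phi=0.6)
        spec, log = select_structure(self._spec(), df)
        assert spec.ar1 is True

    def test_strong_random_slopes_accepted(self):
        accepted = 0
        reps = 8
        for rep in range(reps):
            rng = np.random.default_rng(600 + rep)
            df = _hierarchical_data(rng, n_groups=12, units_per_group=5,
                                    obs_per_unit=12, sd_slope=0.4,
                                    beta_time=0.3)
            spec, log = select_structure(self._spec(), df)
            accepted += spec.random_slope_time
        assert accepted / reps >= 0.8

    def test_pure_noise_keeps_null(self):
        kept_null = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(700 + rep)
            df = pd.DataFrame({
                "y": rng.standard_normal(600),
                "group_id": np.repeat([f"g{i}" for i in range(10)], 60),
                "dyad_id": np.repeat([f"d{i}" for i in range(60)], 10),
                "time": np.tile(np.arange(10.0), 60),
                "phase": "story",
            })
            spec, log = select_structure(self._spec(), df)
            first = log.iloc[0]
            kept_null += not first["accepted"]
        assert kept_null / reps >= 0.6

    def test_random_intercepts_detected(self):
        rng = np.random.default_rng(800)
        df = _hierarchical_data(rng, n_groups=15, units_per_group=6,
                                obs_per_unit=10, sd_group=1.0, sd_unit=1.0)
        _spec, log = select_structure(self._spec(), df)
        assert bool(log.iloc[0]["accepted"])


class TestVarianceExplained:
    def test_fixed_effects_absorb_unit_variance(self):
        rng = np.random.default_rng(12)
        df = _hierarchical_data(rng, n_groups=20, units_per_group=6,
                                obs_per_unit=10, sd_unit=0.2, sd_res=0.8,
                                beta_mutual=1.5)
        out = variance_explained_by_level(BASE_SPEC, df)
        assert 0.0 <= out["group_id"] <= 1.0
        assert out["dyad_id"] > 0.3  # mutual splits dyads, absorbed by fixed term
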