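import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

import liftkin as lk
from liftkin.errors import ConfigurationError, SchemaError


def known_driver_frame(seed, n=2000, n_noise=10, effect=2.0):
    rng = np.random.default_rng(seed)
    cols = ["z_temp"] + [f"noise_{i}" for i in range(n_noise)]
    df = pd.DataFrame(rng.standard_normal((n, len(cols))), columns=cols)
    df["y"] = effect * df["z_temp"] + rng.standard_normal(n)
    return df, cols


class TestDesignMatrix:
    def test_standardization_and_one_hot_counts(self):
        rng = np.random.default_rng(0)
        n = 1000
        df = pd.DataFrame(rng.standard_normal((n, 14)),
                          columns=[f"c{i}" for i in range(14)])
        df["cat3"] = rng.choice(list("abc"), n)
        df["cat6"] = rng.choice(list("uvwxyz"), n)
        df["y"] = rng.standard_normal(n)
        d = lk.build_design_matrix(df, "y",
                                   continuous=[f"c{i}" for i in range(14)],
                                   categorical=["cat3", "cat6"])
        assert d.X.shape == (n, 14 + 2 + 5)  # reference levels dropped
        assert np.all(np.abs(d.X[:, :14].mean(axis=0)) < 1e-10)
        assert np.all(np.abs(d.X[:, :14].std(axis=0) - 1) < 1e-10)

    def test_zero_variance_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": 7.0,
                           "y": [0.1, 0.2, 0.3, 0.4]})
        with pytest.warns(UserWarning, match="zero-variance"):
            d = lk.build_design_matrix(df, "y", continuous=["a", "b"], categorical=[])
        assert d.columns == ["a"]
        assert "b" in d.dropped_covariates

    def test_transform_reuses_training_constants(self):
        df, cols = known_driver_frame(1, n=200)
        d = lk.build_design_matrix(df, "y", continuous=cols, categorical=[])
        shifted = df.copy()
        shifted[cols] += 5.0
        t = d.transform(shifted)
        assert t.columns == d.columns
        assert np.allclose(t.X[:, 0], d.X[:, 0] + 5.0 / d.sds["z_temp"])


class TestLasso:
    def test_full_shrinkage_limit(self):
        df, cols = known_driver_frame(0, n=500)
        d = lk.build_design_matrix(df, "y", continuous=cols, categorical=[])
        fit = lk.fit_lasso(d, lambda_=1e6)
        assert fit.n_nonzero == 0
        assert fit.mu == pytest.approx(df["y"].mean())

    def test_known_driver_recovery(self):
        """y = 2 z_temp + eps: the driver dominates, noise coefficients vanish."""
        df, cols = known_driver_frame(0)
        d = lk.build_design_matrix(df, "y", continuous=cols, categorical=[])
        fit = lk.fit_lasso_cv(d, folds=10, seed=0)
        u = fit.u
        assert u["z_temp"] != 0.0
        noise = u.drop("z_temp").abs()
        assert abs(u["z_temp"]) >= 4.0 * noise.max()
        assert int((noise == 0.0).sum()) >= 8

    def test_seed_determinism(self):
        df, cols = known_driver_frame(5, n=400)
        d = lk.build_design_matrix(df, "y", continuous=cols, categorical=[])
        a = lk.fit_lasso_cv(d, seed=3)
        b = lk.fit_lasso_cv(d, seed=3)
        assert a.lambda_ == b.lambda_
        assert np.array_equal(a.u.to_numpy(), b.u.to_numpy())

    def test_shrinkage_monotonicity_along_path(self):
        df, cols = known_driver_frame(2, n=500)
        d = lk.build_design_matrix(df, "y", continuous=cols, categorical=[])
        lams = np.logspace(-3, 0.5, 12)
        counts = [lk.fit_lasso(d, lam).n_nonzero for lam in lams]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_predict_contracts(self):
        df, cols = known_driver_frame(4, n=300)
        d = lk.build_design_matrix(df, "y", continuous=cols, categorical=[])
        fit = lk.fit_lasso(d, lambda_=1e6)
        assert np.allclose(lk.predict(fit, d), fit.mu)  # all-zero u
        other = lk.build_design_matrix(df, "y", continuous=cols[:3], categorical=[])
        with pytest.raises(SchemaError):
            lk.predict(fit, other)


class TestAccuracy:
    def groups(self, n):
        return pd.DataFrame({
            "genotype": ["G"] * n,
            "date": pd.date_range("2017-04-01", periods=n).date,
            "hour_of_day": 12,
        })

    def test_perfect_and_inverted(self):
        y = np.linspace(0.0, 1.0, 10)
        acc = lk.validate_accuracy(y, y, self.groups(10))
        assert acc.loc[0, "pearson_r"] == pytest.approx(1.0)
        acc = lk.validate_accuracy(y, -y + 3.0, self.groups(10))
        assert acc.loc[0, "pearson_r"] == pytest.approx(-1.0)

    def test_constant_flagged(self):
        y = np.linspace(0.0, 1.0, 10)
        acc = lk.validate_accuracy(y, np.zeros(10), self.groups(10))
        assert np.isnan(acc.loc[0, "pearson_r"])
        assert acc.loc[0, "flag"] == "constant"

    def test_cell_averaging(self):
        """r is computed on (genotype, day, hour) means, not raw values."""
        g = pd.concat([self.groups(3)] * 2, ignore_index=True)
        obs = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0])   # cell means all 2
        pred = np.array([0.0, 1.0, 2.0, 2.0, 3.0, 4.0])  # cell means 1, 2, 3
        acc = lk.validate_accuracy(obs, pred, g)
        assert acc.loc[0, "flag"] == "constant"           # averaged obs constant


class TestSplit:
    def frame(self, n_days):
        return pd.DataFrame({
            "date": np.repeat(pd.date_range("2016-05-01", periods=n_days).date, 3),
            "season": np.repeat(
                ["2016" if i < n_days // 2 else "2017" for i in range(n_days)], 3),
        })

    def test_half_days_parity(self):
        train, valid = lk.split_train_validation(self.frame(10))
        assert train["date"].nunique() == 5
        assert valid["date"].nunique() == 5
        assert set(train["date"]).isdisjoint(valid["date"])

    def test_95_day_split(self):
        train, valid = lk.split_train_validation(self.frame(95))
        assert (train["date"].nunique(), valid["date"].nunique()) == (48, 47)

    def test_by_season(self):
        train, valid = lk.split_train_validation(self.frame(10), scheme="by-season")
        assert set(train["season"]) == {"2016"}
        assert set(valid["season"]) == {"2017"}
        single = self.frame(10).assign(season="2016")
        with pytest.raises(ConfigurationError):
            lk.split_train_validation(single, scheme="by-season")


class TestVariancePartition:
    def test_perfect_predictor_takes_all(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"temperature": rng.uniform(5, 35, 200)})
        df["y"] = 0.02 * df["temperature"] + 0.1
        df["month"] = 5
        part = lk.partition_variance(df, "y", ["temperature", "month"])
        t = part.set_index("factor")
        assert t.loc["temperature", "pct_explained"] == pytest.approx(100.0)
        assert t.loc["residual", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_ss_conservation(self, demo_observations):
        part = lk.partition_variance(demo_observations, "fr2_ratio")
        assert part["sum_sq"].sum() == pytest.approx(part.attrs["total_ss"], rel=1e-8)
        assert part["pct_explained"].sum() == pytest.approx(100.0, abs=0.1)

    def test_orthogonal_factors_order_invariant(self):
        """On a balanced crossed design the two factor SS do not depend on order."""
        levels_a = np.repeat(["a1", "a2"], 50)
        levels_b = np.tile(np.repeat(["b1", "b2"], 25), 2)
        rng = np.random.default_rng(1)
        y = (levels_a == "a2") * 1.0 + (levels_b == "b2") * 0.5 + rng.normal(0, 0.1, 100)
        df = pd.DataFrame({"genotype": levels_a, "plot_id": levels_b, "y": y})
        p1 = lk.partition_variance(df, "y", ["genotype", "plot_id"]).set_index("factor")
        p2 = lk.partition_variance(df, "y", ["plot_id", "genotype"]).set_index("factor")
        for f in ("genotype", "plot_id"):
            assert p1.loc[f, "sum_sq"] == pytest.approx(p2.loc[f, "sum_sq"], rel=1e-10)

    def test_matches_statsmodels_type1_anova(self):
        """Independent oracle: sequential SS equal anova_lm(typ=1) values."""
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "temperature": rng.uniform(0, 30, 300),
            "das": rng.integers(10, 60, 300).astype(float),
        })
        df["y"] = 0.01 * df["temperature"] + 0.002 * df["das"] + rng.normal(0, 0.05, 300)
        mine = lk.partition_variance(df, "y", ["temperature", "das"]).set_index("factor")
        ref = anova_lm(smf.ols("y ~ temperature + das", data=df).fit(), typ=1)
        assert mine.loc["temperature", "sum_sq"] == pytest.approx(
            ref.loc["temperature", "sum_sq"], rel=1e-10)
        assert mine.loc["das", "sum_sq"] == pytest.approx(
            ref.loc["das", "sum_sq"], rel=1e-10)
        assert mine.loc["residual", "sum_sq"] == pytest.approx(
            ref.loc["Residual", "sum_sq"], rel=1e-10)

    def test_temperature_leads_fr2_but_not_fvfm(self, demo_observations):
        """Reoxidation efficiency is temperature-led; PSII efficiency is light-led."""
        fr2 = lk.partition_variance(
            demo_observations, "fr2_ratio", lk.models.FR2_PARTITION_ORDER
        ).set_index("factor")
        explained = fr2.drop("residual")
        assert explained["pct_explained"].idxmax() == "temperature"

        fvfm = lk.partition_variance(
            demo_observations, "fvfm", lk.models.FVFM_PARTITION_ORDER
        ).set_index("factor")
        assert fvfm.loc["temperature", "pct_explained"] < fvfm.loc["ppfd", "pct_explained"]
        assert fvfm.loc["temperature", "pct_explained"] < fvfm.loc["pri", "pct_explained"]


class TestResponseCurves:
    def test_exact_recovery_noiseless_sqrt_law(self):
        t = np.linspace(1.0, 36.0, 100)
        df = pd.DataFrame({"temperature": t, "y": 0.1 + 0.02 * np.sqrt(t)})
        fits = lk.fit_response_curve(df, "y", "temperature", terms=("sqrt",))
        assert len(fits) == 1
        assert fits[0].coefficients["const"] == pytest.approx(0.1, abs=1e-8)
        assert fits[0].coefficients["sqrt(temperature)"] == pytest.approx(0.02, abs=1e-8)
        assert fits[0].r_squared == pytest.approx(1.0)

    def test_one_fit_per_group(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "ppfd": rng.uniform(50, 1500, 500),
            "pri_level": rng.choice([f"q{i}" for i in range(5)], 500),
        })
        df["y"] = 0.8 - 2e-4 * df["ppfd"] + rng.normal(0, 0.01, 500)
        fits = lk.fit_response_curve(df, "y", "ppfd", terms=("linear", "sqrt"),
                                     group_by="pri_level")
        assert len(fits) == 5

    def test_temperature_response_r2_on_campaign(self, demo_observations):
        """Fr2-vs-temperature fits: the cold-sensitive genotype is strongly
        temperature-determined; the tolerant genotype is flatter by design."""
        fits = {f.group: f for f in lk.fit_response_curve(
            demo_observations, "fr2_ratio", "temperature",
            terms=("linear", "sqrt", "square"), group_by="genotype")}
        assert set(fits) == {"Amarok", "S1"}
        assert fits["S1"].r_squared >= 0.8
        assert fits["S1"].r_squared > fits["Amarok"].r_squared

    def test_temperature_response_r2_low_noise_per_species(self):
        """With low noise the per-species temperature fit reaches R^2 >= 0.6."""
        import dataclasses

        cfg = dataclasses.replace(lk.demo_config(seed=2, n_days=7),
                                  noise_sd_rel=0.005, leaf_angle_sd=0.1)
        b = lk.generate_campaign(cfg)
        params, _ = lk.process_table(lk.drop_repeated_position(b.transients),
                                     b.schedule)
        kept, _ = lk.qc_fluorescence(params)
        linked = lk.link_environment(kept, b.env)
        fits = lk.fit_response_curve(linked, "fr2_ratio", "temperature",
                                     terms=("linear", "sqrt", "square"),
                                     group_by="species")
        assert len(fits) == 1
        assert fits[0].r_squared >= 0.6


class TestEndToEndPrediction:
    def test_per_genotype_accuracy(self, demo_observations):
        """Half-days-trained Lasso predicts held-out days per genotype.

        The cold-sensitive genotype's strongly temperature-driven response is
        highly predictable; the tolerant genotype's response is deliberately
        flat in temperature, leaving less signal, hence a lower bound.
        """
        train, valid = lk.split_train_validation(demo_observations)
        d = lk.build_design_matrix(train, "fr2_ratio")
        fit = lk.fit_lasso_cv(d, folds=10, seed=1)
        vd = d.transform(valid)
        pred = lk.predict(fit, vd)
        used = valid[d.continuous + d.categorical + ["fr2_ratio"]].dropna()
        acc = lk.validate_accuracy(
            vd.y, pred, valid.loc[used.index, ["genotype", "date", "hour_of_day"]])
        r = acc.set_index("genotype")["pearson_r"]
        assert r.min() >= 0.6
        assert r.max() >= 0.9
        assert r.mean() >= 0.75
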