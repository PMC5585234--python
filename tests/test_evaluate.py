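"""Anomaly profiles, LOESS, band means, rank statistics, sensitivity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coralclim.ann import AnnConfig
from coralclim.evaluate import (
    band_means,
    compare_means,
    compute_anomalies,
    cross_validation,
    format_correlation_table,
    loess_profile,
    sensitivity_experiment,
    spearman_matrix,
    spearman_test,
    wilcoxon_test,
)
from coralclim.ikfa import fit_ikfa


class TestComputeAnomalies:
    def _modern_env(self, cells, sst):
        idx = pd.MultiIndex.from_tuples(cells, names=["lat_index", "lon_index"])
        return pd.DataFrame(
            {"lat": [c[0] + 0.5 for c in cells],
             "lon": [c[1] + 0.5 for c in cells],
             "mean_sst": sst, "stv": 2.0},
            index=idx,
        )

    def test_predicted_minus_modern(self):
        env = self._modern_env([(0, 0)], [28.0])
        pred = pd.DataFrame({"prediction": [27.0]}, index=env.index)
        out = compute_anomalies(pred, env)
        assert out["anomaly"].iloc[0] == pytest.approx(-1.0)

    def test_cells_without_reference_dropped(self):
        env = self._modern_env([(0, 0)], [28.0])
        idx = pd.MultiIndex.from_tuples([(0, 0), (5, 5)],
                                        names=["lat_index", "lon_index"])
        pred = pd.DataFrame({"prediction": [27.0, 26.0]}, index=idx)
        assert len(compute_anomalies(pred, env)) == 1

    def test_empty_overlap_raises(self):
        env = self._modern_env([(0, 0)], [28.0])
        idx = pd.MultiIndex.from_tuples([(9, 9)], names=["lat_index", "lon_index"])
        pred = pd.DataFrame({"prediction": [27.0]}, index=idx)
        with pytest.raises(ValueError):
            compute_anomalies(pred, env)

    def test_null_scenario_near_zero(self, world, fast_ann_config):
        """Modern assemblages against the modern field: anomalies ~ 0."""
        model = fit_ikfa(world.calibration, world.env["mean_sst"], k=4)
        from coralclim.ikfa import predict_ikfa

        pred = predict_ikfa(model, world.calibration)
        out = compute_anomalies(pred, world.modern_env, method="ikfa")
        assert abs(out["anomaly"].mean()) < 0.2


class TestLoess:
    def test_constant_values(self):
        x = np.linspace(-30, 30, 40)
        curve = loess_profile(x, np.full(40, 3.0), span=0.5)
        np.testing.assert_allclose(curve["value"], 3.0, atol=1e-10)

    @pytest.mark.parametrize("span", [0.3, 0.8, 1.0])
    def test_linear_exact(self, span):
        x = np.linspace(-30, 30, 50)
        y = 2.0 + 0.5 * x
        curve = loess_profile(x, y, span=span, degree=1)
        np.testing.assert_allclose(curve["value"], 2.0 + 0.5 * curve["lat"],
                                   atol=1e-8)

    def test_quadratic_exact_with_degree_2(self):
        x = np.linspace(-10, 10, 60)
        y = 1.0 - 0.05 * x**2
        curve = loess_profile(x, y, span=0.8, degree=2)
        np.testing.assert_allclose(curve["value"], 1.0 - 0.05 * curve["lat"] ** 2,
                                   atol=1e-6)

    def test_matches_statsmodels_lowess_degree_1(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(-30, 30, 80))
        y = np.sin(x / 10) + rng.normal(0, 0.05, 80)
        ours = loess_profile(x, y, span=0.5, degree=1, grid=x)["value"].to_numpy()
        theirs = sm.nonparametric.lowess(y, x, frac=0.5, it=0, return_sorted=False)
        # same family of estimators; agreement to a few percent of the range
        assert np.abs(ours - theirs).max() < 0.1

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            loess_profile([0.0, 1.0], [1.0, 2.0], span=0.5, degree=2)

    def test_tiny_span_widened(self):
        x = np.linspace(0, 10, 20)
        curve = loess_profile(x, x, span=0.05, degree=1)
        assert np.isfinite(curve["value"]).all()


class TestBandMeans:
    def test_single_point_per_band(self):
        prof = pd.DataFrame({"lat": [-7.5, -2.5, 2.5], "anomaly": [1.0, 2.0, 3.0]})
        out = band_means(prof, width=5.0)
        np.testing.assert_allclose(out["mean"].to_numpy(), [1.0, 2.0, 3.0])
        assert list(out.index) == [-7.5, -2.5, 2.5]

    def test_mean_within_band(self):
        prof = pd.DataFrame({"lat": [1.0, 2.0, 3.0], "anomaly": [-1.0, -1.0, 3.0]})
        out = band_means(prof, width=5.0)
        assert out["mean"].iloc[0] == pytest.approx(1 / 3)

    def test_empty_bands_reported_missing(self):
        prof = pd.DataFrame({"lat": [2.0, 12.0], "anomaly": [1.0, 2.0]})
        out = band_means(prof, width=5.0, lat_range=(0.0, 14.0))
        assert np.isnan(out.loc[7.5, "mean"])
        assert out.loc[7.5, "n"] == 0

    def test_recovers_imposed_piecewise_function(self, world):
        """Band means of the true anomaly match its band-averaged values."""
        lat = world.modern_env["lat"].to_numpy()
        truth = world.config.anomaly.mean_shift(lat)
        prof = pd.DataFrame({"lat": lat, "anomaly": truth})
        out = band_means(prof, width=5.0).dropna()
        centers = out.index.to_numpy()
        expected = world.config.anomaly.mean_shift(centers)
        # inner-band agreement is exact; transition bands differ by curvature
        inner = (np.abs(centers) <= 10) | (np.abs(centers) >= 27.5)
        np.testing.assert_allclose(out["mean"].to_numpy()[inner],
                                   expected[inner], atol=1e-10)


def _exact_spearman_p(x, y):
    """Independent enumeration oracle via the d^2 statistic definition."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    n = len(x)

    def rho_of(perm):
        d = rx[list(perm)] - ry
        return 1 - 6 * (d**2).sum() / (n * (n**2 - 1))

    obs = rho_of(range(n))
    count = sum(
        abs(rho_of(p)) >= abs(obs) - 1e-12
        for p in itertools.permutations(range(n))
    )
    import math

    return obs, count / math.factorial(n)


class TestRankStatistics:
    def test_self_correlation(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        rho, _ = spearman_test(x, x)
        assert rho == pytest.approx(1.0)

    def test_negation(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        rho, _ = spearman_test(x, -x)
        assert rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_null_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        x, y = rng.normal(size=n), rng.normal(size=n)
        rho, p = spearman_test(x, y)
        rho_o, p_o = _exact_spearman_p(x, y)
        assert rho == pytest.approx(rho_o)
        assert p == pytest.approx(p_o)

    def test_wilcoxon_identical_series(self):
        x = np.arange(8.0)
        assert wilcoxon_test(x, x) == 1.0

    def test_wilcoxon_shifted_constant_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        assert wilcoxon_test(x, x + 5.0) < 0.05

    def test_wilcoxon_matches_sign_flip_enumeration(self):
        """scipy's exact signed-rank p equals full 2^n sign enumeration."""
        from scipy.stats import rankdata

        rng = np.random.default_rng(2)
        d = rng.normal(size=7)
        p = wilcoxon_test(d, np.zeros(7))
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = len(d)
        stats = []
        for signs in itertools.product([0, 1], repeat=n):
            stats.append(ranks[np.array(signs, dtype=bool)].sum())
        stats = np.asarray(stats)
        mu = ranks.sum() / 2
        p_exact = np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-12)
        assert p == pytest.approx(p_exact)


class TestSeriesComparison:
    def _bands(self):
        idx = np.arange(-32.5, 33, 5.0)
        rng = np.random.default_rng(0)
        base = np.sin(idx / 20)
        return pd.DataFrame(
            {
                "a": base + rng.normal(0, 0.1, len(idx)),
                "b": base + rng.normal(0, 0.1, len(idx)),
                "c": rng.normal(0, 1.0, len(idx)),
            },
            index=idx,
        )

    def test_matrix_diagonal_and_symmetry(self):
        rho, p = spearman_matrix(self._bands())
        assert (np.diag(rho) == 1.0).all()
        pd.testing.assert_frame_equal(rho, rho.T)

    def test_min_shared_bands_respected(self):
        df = self._bands()
        df.loc[df.index[:-3], "c"] = np.nan  # only 3 shared bands left
        rho, p = spearman_matrix(df, min_shared=4)
        assert np.isnan(rho.loc["a", "c"])

    def test_formatted_table_layout(self):
        rho, p = spearman_matrix(self._bands())
        table = format_correlation_table(rho, p)
        assert table.loc["b", "a"] != "" and table.loc["a", "b"] != ""
        assert (np.diag(table) == "").all()

    def test_identical_series_indistinguishable(self):
        idx = np.arange(-30.0, 31.0, 5.0)
        s = pd.DataFrame({"a": np.sin(idx / 9), "b": np.sin(idx / 9)}, index=idx)
        res = compare_means(s)
        assert res["wilcoxon_p"].loc["a", "b"] == 1.0

    def test_large_shift_detected(self):
        idx = np.arange(-30.0, 31.0, 5.0)
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.2, len(idx))
        s = pd.DataFrame({"a": a, "b": a + 4.0}, index=idx)
        res = compare_means(s)
        assert res["wilcoxon_p"].loc["a", "b"] < 0.05
        assert res["anova_p"] < 0.05

    def test_latitude_range_restriction(self):
        idx = np.arange(-50.0, 51.0, 5.0)
        s = pd.DataFrame({"a": idx, "b": idx}, index=idx)
        res = compare_means(s, lat_range=(-32, 33))
        assert res["means"]["a"] == pytest.approx(
            idx[(idx >= -32) & (idx <= 33)].mean()
        )


class TestCrossValidation:
    def test_resubstitution_vs_loo_optimism(self, world):
        """LOO error should not beat apparent error (checked for the factor
        branch across seeds of small random calibrations)."""
        rng = np.random.default_rng(0)
        wins = 0
        trials = 6
        for _ in range(trials):
            X = rng.random((25, 6)) ** 2
            X = X / X.sum(axis=1, keepdims=True)
            df = pd.DataFrame(X, columns=[f"t{j}" for j in range(6)])
            y = pd.Series(X @ rng.normal(size=6) + rng.normal(0, 0.3, 25))
            resub = cross_validation(df, y, method="ikfa", mode="resubstitution", k=3)
            loo = cross_validation(df, y, method="ikfa", mode="leave_one_out", k=3)
            if np.sqrt((loo.deviation**2).mean()) >= np.sqrt(
                (resub.deviation**2).mean()
            ):
                wins += 1
        assert wins == trials

    def test_methods_agree_on_synthetic_world(self, world, fast_ann_config):
        """ANN and factor-analysis deviations within 1 degC RMSE of each other."""
        rm = {}
        for method in ("ikfa", "ann"):
            dev = cross_validation(
                world.calibration, world.env["mean_sst"], method=method,
                mode="resubstitution", ann_config=fast_ann_config, k=4,
            )
            rm[method] = float(np.sqrt((dev.deviation**2).mean()))
        assert abs(rm["ann"] - rm["ikfa"]) < 1.0

    def test_unknown_method_rejected(self, world):
        with pytest.raises(ValueError):
            cross_validation(world.calibration, world.env["mean_sst"],
                             method="wa-pls")


class TestSensitivity:
    def test_full_fraction_is_reference(self, world, fast_ann_config):
        res = sensitivity_experiment(
            world.calibration.iloc[:40], world.env["mean_sst"].iloc[:40],
            world.fossil_matrix, world.modern_env,
            species_fractions=(1.0,), n_reps=1, base_seed=0,
            ann_config=fast_ann_config, k=3,
        )
        assert res["ann_anomaly_shift"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["ikfa_anomaly_shift"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_single_species_pool_refused(self):
        X = pd.DataFrame({"only": np.ones(10)})
        with pytest.raises(ValueError):
            fit_ikfa(X, pd.Series(np.arange(10.0), name="e"), k=2)
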