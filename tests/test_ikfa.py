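"""Factor-analysis transfer function: SVD oracle, varimax, projection."""

import numpy as np
import pandas as pd
import pytest

from coralclim.ikfa import (
    fit_ikfa,
    predict_ikfa,
    varimax,
    varimax_criterion,
)


def _random_props(rng, n, p):
    """Random row-stochastic matrix."""
    X = rng.random((n, p)) ** 2
    return X / X.sum(axis=1, keepdims=True)


def _props_df(X, taxa=None):
    taxa = taxa or [f"t{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=taxa)


def brute_force_varimax_2d(L, step=0.001):
    """Oracle: scan planar rotation angles for the best varimax criterion."""
    best = -np.inf
    for theta in np.arange(0.0, np.pi / 2, step):
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        best = max(best, varimax_criterion(L @ R))
    return best


class TestVarimax:
    def test_k1_identity(self):
        L = np.random.default_rng(0).normal(size=(6, 1))
        Lr, R = varimax(L)
        np.testing.assert_allclose(Lr, L)
        np.testing.assert_allclose(R, [[1.0]])

    def test_axis_aligned_fixed_point(self):
        # block matrix already varimax-optimal: criterion cannot improve
        L = np.array([[2.0, 0], [1.5, 0], [0, 1.0], [0, 0.8], [0, 1.2]])
        Lr, R = varimax(L)
        assert varimax_criterion(Lr) == pytest.approx(varimax_criterion(L), abs=1e-10)
        # rotation is a signed permutation
        np.testing.assert_allclose(np.abs(R) @ np.abs(R.T), np.eye(2), atol=1e-8)

    def test_matches_angle_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            L = rng.normal(size=(6, 2))
            Lr, _ = varimax(L)
            assert varimax_criterion(Lr) == pytest.approx(
                brute_force_varimax_2d(L), abs=1e-4
            )

    def test_orthogonality_and_communalities(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n, k = rng.integers(4, 12), rng.integers(2, 5)
            L = rng.normal(size=(n, k))
            Lr, R = varimax(L)
            np.testing.assert_allclose(R.T @ R, np.eye(k), atol=1e-10)
            np.testing.assert_allclose(
                (Lr**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-10
            )
            assert varimax_criterion(Lr) >= varimax_criterion(L) - 1e-12


class TestFit:
    def test_rank2_archetype_recovery(self):
        """Mixtures of two archetype assemblages: k=2 reconstructs exactly and a
        linear-in-mixing environment regresses to machine precision."""
        rng = np.random.default_rng(5)
        a1 = np.array([0.6, 0.3, 0.05, 0.05, 0.0])
        a2 = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        w = rng.random(40)
        X = np.outer(w, a1) + np.outer(1 - w, a2)
        env = pd.Series(20.0 + 8.0 * w, name="mean_sst")
        model = fit_ikfa(_props_df(X), env, k=2)
        # pre-regression reconstruction of the scaled matrix
        W = X / np.linalg.norm(X, axis=1, keepdims=True)
        F = model.calibration_stats["loadings"]
        recon = F @ model.taxon_scores.T
        assert np.abs(recon - W).max() < 1e-8
        # env is linear in the mixing weight, hence linear in the raw matrix:
        # the no-scaling mode regresses it away to machine precision
        raw = fit_ikfa(_props_df(X), env, k=2, row_norm="none")
        assert raw.calibration_stats["rmse"]["mean_sst"] < 1e-6

    def test_full_rank_square_perfect_reconstruction(self):
        rng = np.random.default_rng(6)
        X = _random_props(rng, 6, 6)
        model = fit_ikfa(_props_df(X), pd.Series(rng.normal(size=6), name="e"), k=6)
        W = X / np.linalg.norm(X, axis=1, keepdims=True)
        recon = model.calibration_stats["loadings"] @ model.taxon_scores.T
        np.testing.assert_allclose(recon, W, atol=1e-8)

    def test_constant_env_regresses_to_intercept(self):
        rng = np.random.default_rng(7)
        X = _random_props(rng, 12, 5)
        model = fit_ikfa(_props_df(X), pd.Series(np.full(12, 23.0), name="e"), k=3)
        beta = model.coefficients["e"]
        assert beta[0] == pytest.approx(23.0, abs=1e-10)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-10)

    def test_k_exceeding_rank_rejected(self):
        rng = np.random.default_rng(8)
        X = _random_props(rng, 10, 4)
        X[5:] = X[:5]  # rank <= 5 anyway; k > n_taxa must fail
        with pytest.raises(ValueError):
            fit_ikfa(_props_df(X), pd.Series(rng.normal(size=10), name="e"), k=5)

    def test_rmse_monotone_in_k(self):
        rng = np.random.default_rng(9)
        X = _random_props(rng, 30, 8)
        env = pd.Series(X @ rng.normal(size=8) + 0.1 * rng.normal(size=30), name="e")
        rmses = [
            fit_ikfa(_props_df(X), env, k=k).calibration_stats["rmse"]["e"]
            for k in range(1, 7)
        ]
        assert all(b <= a + 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_rotation_absorbed_by_regression(self):
        """Fitted calibration values are invariant to the varimax rotation."""
        rng = np.random.default_rng(10)
        X = _random_props(rng, 25, 6)
        env = pd.Series(X @ rng.normal(size=6), name="e")
        model = fit_ikfa(_props_df(X), env, k=3)
        # unrotated fit: regress env on raw SVD loadings
        W = X / np.linalg.norm(X, axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        F = U[:, :3] * s[:3]
        D = np.column_stack([np.ones(25), F])
        beta, *_ = np.linalg.lstsq(D, env.to_numpy(), rcond=None)
        np.testing.assert_allclose(
            np.asarray(model.calibration_stats["fitted"]["e"]), D @ beta, atol=1e-8
        )


class TestPredict:
    def test_calibration_self_consistency(self):
        rng = np.random.default_rng(11)
        X = _random_props(rng, 10, 5)
        df = _props_df(X)
        env = pd.Series(rng.normal(size=10), name="e")
        model = fit_ikfa(df, env, k=5)  # k = matrix rank
        pred = predict_ikfa(model, df)
        np.testing.assert_allclose(
            pred["pred_e"].to_numpy(),
            np.asarray(model.calibration_stats["fitted"]["e"]),
            atol=1e-10,
        )
        assert (pred["communality"] >= 1 - 1e-8).all()
        assert not pred["no_analog"].any()

    def test_orthogonal_assemblage_flagged_no_analog(self):
        X = np.array([[0.5, 0.5, 0.0, 0.0], [0.4, 0.6, 0.0, 0.0],
                      [0.6, 0.4, 0.0, 0.0], [0.55, 0.45, 0.0, 0.0]])
        # add tiny noise to make the first two columns span rank 2
        rng = np.random.default_rng(12)
        X[:, :2] += rng.normal(0, 0.01, (4, 2))
        X = np.abs(X) / np.abs(X).sum(axis=1, keepdims=True)
        df = _props_df(X)
        model = fit_ikfa(df, pd.Series([1.0, 2, 3, 4], name="e"), k=2)
        fossil = _props_df(np.array([[0.0, 0.0, 0.5, 0.5]]))
        pred = predict_ikfa(model, fossil)
        assert pred["communality"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert bool(pred["no_analog"].iloc[0])

    def test_all_zero_fossil_row_missing(self):
        rng = np.random.default_rng(13)
        df = _props_df(_random_props(rng, 8, 4))
        model = fit_ikfa(df, pd.Series(rng.normal(size=8), name="e"), k=2)
        fossil = _props_df(np.zeros((1, 4)))
        pred = predict_ikfa(model, fossil)
        assert np.isnan(pred["pred_e"].iloc[0])
        assert bool(pred["no_analog"].iloc[0])

    def test_unseen_taxa_zero_filled(self):
        rng = np.random.default_rng(14)
        df = _props_df(_random_props(rng, 8, 4))
        model = fit_ikfa(df, pd.Series(rng.normal(size=8), name="e"), k=2)
        fossil = pd.DataFrame({"t0": [0.5], "t1": [0.5], "new_taxon": [0.0]})
        pred = predict_ikfa(model, fossil)
        assert np.isfinite(pred["pred_e"].iloc[0])

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(15)
        df = _props_df(_random_props(rng, 10, 5))
        env = pd.Series(rng.normal(size=10), name="e")
        model = fit_ikfa(df, env, k=3)
        p = tmp_path / "model.json"
        model.to_json(p)
        from coralclim.ikfa import IkfaModel

        loaded = IkfaModel.from_json(p)
        a = predict_ikfa(model, df)
        b = predict_ikfa(loaded, df)
        pd.testing.assert_frame_equal(a, b)


def test_parameter_recovery_on_synthetic_world(world):
    """Fossil SST predicted within 0.5 degC mean signed error at k=4."""
    model = fit_ikfa(world.calibration, world.env["mean_sst"], k=4)
    pred = predict_ikfa(model, world.fossil_matrix)
    truth = world.fossil_field.env_table()["mean_sst"]
    shared = pred.index.intersection(truth.index)
    signed = (pred.loc[shared, "pred_mean_sst"] - truth.loc[shared]).mean()
    assert abs(signed) < 0.5
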