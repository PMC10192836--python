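"""Prediction contracts: similarity kernel, KRR dual/primal
equivalence, LRR against the normal-equation oracle, leak-free confound
handling, grouped fold construction, and nested-CV hyperparameter
selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from parcgrad import predict as pr


class TestSimilarityKernel:
    def test_duplicated_and_reversed_subjects(self):
        x = np.array([[1.0, 2, 3], [1, 2, 3], [3, 2, 1]])
        k = pr.similarity_kernel(x)
        assert k[0, 1] == pytest.approx(1.0)
        assert k[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(k), 1.0)

    def test_random_long_vectors_near_zero(self, rng):
        d = 5000
        k = pr.similarity_kernel(rng.standard_normal((5, d)))
        off = k[np.triu_indices(5, 1)]
        assert np.abs(off).max() < 3.0 / np.sqrt(d)

    def test_zero_variance_row_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pr.similarity_kernel(np.vstack([np.ones(4), np.arange(4.0)]))


class TestSimilarityWeightedPrediction:
    def test_worked_two_subject_example(self):
        got = pr.similarity_weighted_prediction(
            np.array([0.8, 0.1]), np.array([10.0, 100.0])
        )
        assert got == pytest.approx(18.0)

    def test_zero_similarity_and_single_subject(self):
        assert pr.similarity_weighted_prediction(np.zeros(3), np.arange(3.0)) == 0.0
        assert pr.similarity_weighted_prediction(
            np.array([1.0]), np.array([7.0])
        ) == pytest.approx(7.0)


class TestKRR:
    def test_interpolation_at_lambda_zero(self, rng):
        x = rng.standard_normal((6, 30))
        k = pr.similarity_kernel(x)
        y = rng.standard_normal(6)
        pred = pr.krr_fit_predict(k, y, k[2][None, :], 0.0)
        assert pred[0] == pytest.approx(y[2], abs=1e-8)

    def test_large_lambda_shrinks_to_mean(self, rng):
        x = rng.standard_normal((8, 30))
        k = pr.similarity_kernel(x)
        y = rng.standard_normal(8)
        pred = pr.krr_fit_predict(k, y, k[:3], 1e9)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-6)

    @given(st.integers(0, 300))
    def test_dual_matches_primal_ridge_oracle(self, seed):
        # with a linear kernel K = X X^T, dual KRR must equal primal ridge
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((5, 3))
        x_te = rng.standard_normal((2, 3))
        y = rng.standard_normal(5)
        lam = float(rng.uniform(0.05, 2.0))
        pred_dual = pr.krr_fit_predict(x @ x.T, y, x_te @ x.T, lam)
        yc = y - y.mean()
        beta = np.linalg.solve(x.T @ x + lam * np.eye(3), x.T @ yc)
        pred_primal = x_te @ beta + y.mean()
        np.testing.assert_allclose(pred_dual, pred_primal, atol=1e-8)

    def test_sweep_matches_single_solves(self, rng):
        x = rng.standard_normal((10, 20))
        k = pr.similarity_kernel(x)
        y = rng.standard_normal(10)
        tr, te = np.arange(7), np.arange(7, 10)
        lams = np.array([0.01, 0.5, 3.0])
        sweep = pr._krr_sweep(k[np.ix_(tr, tr)], y[tr], k[np.ix_(te, tr)], lams)
        for i, lam in enumerate(lams):
            single = pr.krr_fit_predict(
                k[np.ix_(tr, tr)], y[tr], k[np.ix_(te, tr)], lam
            )
            np.testing.assert_allclose(sweep[i], single, atol=1e-8)


class TestLRR:
    def test_large_lambda_shrinks_to_mean(self, rng):
        x = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        pred = pr.lrr_fit_predict(x, y, x[:3], 1e12)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-4)

    def test_noiseless_recovery_small_lambda(self, rng):
        x = rng.standard_normal((30, 4))
        beta = rng.standard_normal(4)
        y = x @ beta
        pred = pr.lrr_fit_predict(x, y, x[:5], 1e-10)
        np.testing.assert_allclose(pred, y[:5], atol=1e-5)

    @given(st.integers(0, 300))
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((10, 4))
        x_te = rng.standard_normal((3, 4))
        y = rng.standard_normal(10)
        lam = float(rng.uniform(0.05, 2.0))
        pred = pr.lrr_fit_predict(x, y, x_te, lam)
        mu, sd = x.mean(0), x.std(0)
        xs, xts = (x - mu) / sd, (x_te - mu) / sd
        # oracle: centered normal equations with explicit intercept = ybar
        yc = y - y.mean()
        xc = xs - xs.mean(0)
        beta = np.linalg.solve(xc.T @ xc + lam * np.eye(4), xc.T @ yc)
        oracle = (xts - xs.mean(0)) @ beta + y.mean()
        np.testing.assert_allclose(pred, oracle, atol=1e-7)

    def test_sweep_matches_single_fits(self, rng):
        x = rng.standard_normal((12, 5))
        y = rng.standard_normal(12)
        lams = np.array([0.05, 0.5, 1.0])
        sweep = pr._lrr_sweep(x[:9], y[:9], x[9:], lams)
        for i, lam in enumerate(lams):
            np.testing.assert_allclose(
                sweep[i], pr.lrr_fit_predict(x[:9], y[:9], x[9:], lam), atol=1e-7
            )


def confound_frame(rng, n):
    return pd.DataFrame(
        {
            "age": rng.uniform(20, 40, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "FD": rng.lognormal(-1.8, 0.4, n),
            "DVARS": rng.lognormal(0, 0.3, n),
        }
    )


class TestConfounds:
    def test_train_residuals_orthogonal(self, rng):
        c = confound_frame(rng, 50)
        y = rng.standard_normal(50)
        model = pr.fit_confounds(y, c)
        resid = model.apply(y, c)
        for col in c:
            assert abs(resid @ (c[col] - c[col].mean())) < 1e-8

    def test_pure_confound_signal_removed(self, rng):
        c = confound_frame(rng, 40)
        y = 3.0 * c["FD"].to_numpy() - 1.0
        model = pr.fit_confounds(y, c)
        np.testing.assert_allclose(model.apply(y, c), 0.0, atol=1e-10)

    def test_test_fold_uses_training_coefficients(self, rng):
        c_tr = confound_frame(rng, 60)
        c_te = confound_frame(rng, 20) + 5.0  # shifted confound distribution
        y_tr = 2.0 * c_tr["age"].to_numpy() + rng.standard_normal(60)
        y_te = 2.0 * c_te["age"].to_numpy() + rng.standard_normal(20)
        model = pr.fit_confounds(y_tr, c_tr)
        applied = pr.apply_confounds(y_te, c_te, model)
        refit = pr.fit_confounds(y_te, c_te).apply(y_te, c_te)
        # no-leak contract: applying train coefficients is NOT a refit
        assert not np.allclose(applied, refit)
        assert abs(refit.mean()) < 1e-8  # refit recenters; applied need not

    def test_collinear_covariate_dropped(self, rng):
        c = confound_frame(rng, 30)
        c["FD2"] = 2.0 * c["FD"]
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="collinear"):
            model = pr.fit_confounds(y, c)
        assert not model.kept[list(c.columns).index("FD2")]


class TestMakeFolds:
    def test_site_cluster_enumeration_count(self):
        site = np.repeat(np.arange(9), 12)
        structure = pd.DataFrame({"family_id": np.arange(108), "site_id": site})
        scheme = pr.CVScheme(kind="leave_p_siteclusters", p_out=3)
        folds = pr.make_folds(structure, scheme)
        assert len(folds) == 84
        held = {tuple(sorted(set(site[f.test]))) for f in folds}
        assert len(held) == 84  # every 3-subset appears exactly once

    def test_singleton_families_equal_folds(self):
        structure = pd.DataFrame(
            {"family_id": np.arange(100), "site_id": np.zeros(100, int)}
        )
        scheme = pr.CVScheme(kind="repeated_kfold", k=20, replications=1, seed=0)
        folds = pr.make_folds(structure, scheme)
        assert len(folds) == 20
        assert all(len(f.test) == 5 for f in folds)

    def test_no_group_ever_split(self):
        rng = np.random.default_rng(0)
        fam = rng.integers(0, 18, size=60)
        structure = pd.DataFrame({"family_id": fam, "site_id": fam % 5})
        scheme = pr.CVScheme(kind="repeated_kfold", k=5, replications=400, seed=1)
        for fold in pr.make_folds(structure, scheme):
            assert not set(fam[fold.train]) & set(fam[fold.test])

    def test_folds_partition_subjects(self):
        structure = pd.DataFrame(
            {"family_id": np.arange(30) // 2, "site_id": np.zeros(30, int)}
        )
        scheme = pr.CVScheme(kind="repeated_kfold", k=5, replications=3, seed=2)
        folds = pr.make_folds(structure, scheme)
        for rep in range(3):
            tests = np.sort(
                np.concatenate([f.test for f in folds if f.replication == rep])
            )
            np.testing.assert_array_equal(tests, np.arange(30))


def planted_features(rng, n=80, signal_res=8):
    """Features at three resolutions; only `signal_res` carries signal."""
    y = rng.standard_normal(n)
    feats = {}
    for res in (4, signal_res, 16):
        noise = rng.standard_normal((n, 30))
        if res == signal_res:
            noise[:, 0] = y + 0.3 * rng.standard_normal(n)
        feats[res] = noise
    return feats, y


class TestNestedCV:
    def _structure(self, n):
        return pd.DataFrame(
            {"family_id": np.arange(n), "site_id": np.arange(n) % 4}
        )

    def test_single_point_grids_reduce_to_plain_cv(self, rng):
        n = 40
        x = rng.standard_normal((n, 20))
        y = x[:, 0] + 0.5 * rng.standard_normal(n)
        conf = confound_frame(rng, n)
        structure = self._structure(n)
        scheme = pr.CVScheme(kind="repeated_kfold", k=4, replications=1, seed=5)
        spec = pr.RidgeSpec(model="krr", lambda_grid=[0.5])
        df = pr.nested_cv({10: x}, y, conf, structure, scheme, spec)
        # manual plain CV over the same folds
        k = pr.similarity_kernel(x)
        for _, row in df.iterrows():
            folds = pr.make_folds(structure, scheme)
            fold = [
                f
                for f in folds
                if f.replication == row["replication"] and f.fold == row["fold"]
            ][0]
            cm = pr.fit_confounds(y[fold.train], conf.iloc[fold.train])
            ytr = cm.apply(y[fold.train], conf.iloc[fold.train])
            yte = cm.apply(y[fold.test], conf.iloc[fold.test])
            pred = pr.krr_fit_predict(
                k[np.ix_(fold.train, fold.train)],
                (ytr - ytr.mean()) / ytr.std(),
                k[np.ix_(fold.test, fold.train)],
                0.5,
            )
            r, _ = pr.pearson_accuracy(pred, yte)
            assert row["accuracy"] == pytest.approx(r, abs=1e-10)

    def test_planted_resolution_recovered(self, rng):
        feats, y = planted_features(rng)
        n = len(y)
        conf = confound_frame(rng, n)
        scheme = pr.CVScheme(kind="repeated_kfold", k=5, replications=2, seed=3)
        spec = pr.RidgeSpec(model="krr", lambda_grid=[0.1, 1.0, 5.0])
        df = pr.nested_cv(feats, y, conf, self._structure(n), scheme, spec)
        modal = df["resolution"].mode().iloc[0]
        assert modal == 8

    def test_chosen_hyperparameters_from_grids(self, rng):
        feats, y = planted_features(rng)
        conf = confound_frame(rng, len(y))
        scheme = pr.CVScheme(kind="leave_p_siteclusters", p_out=1)
        spec = pr.RidgeSpec(model="lrr", lambda_grid=[0.05, 0.5])
        df = pr.nested_cv(feats, y, conf, self._structure(len(y)), scheme, spec)
        assert set(df["resolution"]) <= {4, 8, 16}
        assert set(df["lambda"]) <= {0.05, 0.5}
        assert np.all(df["accuracy"].abs() <= 1.0)

    def test_tie_break_prefers_small_lambda_then_resolution(self):
        scores = np.array([[0.5, 0.5], [0.5, 0.2]])
        ri, li = pr._select_best(scores, [4, 8], np.array([0.1, 1.0]))
        assert (ri, li) == (0, 0)


class TestAggregate:
    def _df(self):
        rows = []
        for beh, accs in [("a", [0.2, 0.4]), ("b", [0.6, 0.8])]:
            for fold, acc in enumerate(accs):
                rows.append(
                    dict(
                        behavior=beh, approach="m", replication=0, fold=fold,
                        accuracy=acc, n_train=30, n_test=10,
                    )
                )
        return pd.DataFrame(rows)

    def test_behavior_and_category_means(self):
        df = self._df()
        by_beh = pr.aggregate_accuracy(df, "behavior")
        assert by_beh.set_index("behavior").loc["a", "accuracy"] == pytest.approx(0.3)
        by_cat = pr.aggregate_accuracy(df, "category", {"a": "task", "b": "task"})
        assert by_cat["accuracy"].iloc[0] == pytest.approx(0.5)

    def test_fold_permutation_invariant(self):
        df = self._df()
        shuffled = df.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(
            pr.aggregate_accuracy(df, "behavior"),
            pr.aggregate_accuracy(shuffled, "behavior"),
        )

    def test_missing_folds_detected(self):
        df = self._df().iloc[:-1]
        with pytest.raises(ValueError, match="missing folds"):
            pr.aggregate_accuracy(df, "behavior")
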