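import json

import numpy as np
import pytest

from ligandfield import fieldgen, qsar
from ligandfield.qsar import (FieldPLS, bootstrap_validate, column_filter,
                              external_r2pred, field_contributions, fit_pls,
                              load_model, loo_q2, non_cv_stats,
                              predict_with_payload, select_components,
                              y_scramble)


def random_problem(rng, n=12, p=30, informative=3, noise=0.1):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:informative] = rng.normal(size=informative)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestNipals:
    def test_full_rank_equals_ols(self, rng):
        # with ncomp = p on a full-rank tall problem, PLS1 reproduces OLS
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        m = fit_pls(X, y, 4)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.allclose(m.coef, beta, atol=1e-8)
        assert np.allclose(m.predict(X), Xc @ beta + y.mean(), atol=1e-8)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(rng, n=15, p=8)
        for ncomp in (1, 2, 3):
            mine = fit_pls(X, y, ncomp)
            ref = sklearn.PLSRegression(n_components=ncomp, scale=False)
            ref.fit(X, y)
            assert np.allclose(mine.coef, ref.coef_.ravel(), atol=1e-8)

    def test_component_cap(self, rng):
        X, y = random_problem(rng, n=5, p=30)
        m = fit_pls(X, y, 50)
        assert m.n_components <= 4  # capped at n - 1

    def test_input_validation(self, rng):
        X, y = random_problem(rng)
        with pytest.raises(ValueError):
            fit_pls(X, y[:-1], 2)
        with pytest.raises(ValueError):
            fit_pls(X, y, 0)
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_pls(Xn, y, 2)


class TestLoo:
    def test_equals_naive_double_loop(self, rng):
        X, y = random_problem(rng)
        ncomp = 3
        q2, sep = loo_q2(X, y, ncomp)
        press = 0.0
        for i in range(len(y)):
            Xi = np.delete(X, i, axis=0)
            yi = np.delete(y, i)
            press += (y[i] - fit_pls(Xi, yi, ncomp).predict(X[i:i+1])[0]) ** 2
        sst = ((y - y.mean()) ** 2).sum()
        assert q2 == pytest.approx(1 - press / sst, abs=1e-10)
        assert sep == pytest.approx(np.sqrt(press / (len(y) - ncomp - 1)),
                                    abs=1e-10)

    def test_select_components_tie_breaks_to_fewer(self, rng):
        # duplicated informative column: component 2 adds nothing
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, x])
        y = x.ravel()
        best, path = select_components(X, y, max_ncomp=3)
        assert best == 1
        assert path[0] == pytest.approx(max(path), abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            loo_q2(np.zeros((2, 3)), np.array([1.0, 2.0]), 1)


class TestStatistics:
    def test_external_r2pred_spreadsheet(self):
        # hand-worked example: PRES = 0.09+0.04, SD = 1+0.25
        y_test = [7.0, 8.5]
        yhat = [7.3, 8.3]
        train_mean = 8.0
        r2p, pres, sd = external_r2pred(y_test, yhat, train_mean)
        assert pres == pytest.approx(0.13)
        assert sd == pytest.approx(1.25)
        assert r2p == pytest.approx(1 - 0.13 / 1.25)

    def test_non_cv_stats_perfect_fit(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        m = fit_pls(X, y, 3)
        r2, see, f = non_cv_stats(m, X, y)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert see == pytest.approx(0.0, abs=1e-6)

    def test_bootstrap_deterministic_given_seed(self, rng):
        X, y = random_problem(rng, n=15)
        a = bootstrap_validate(X, y, 2, n_runs=10, seed=7)
        b = bootstrap_validate(X, y, 2, n_runs=10, seed=7)
        assert a == b
        assert a["n_runs"] == 10

    def test_scramble_excludes_identity_and_is_null(self, rng):
        X, y = random_problem(rng, n=14, noise=0.05)
        real_q2, _ = loo_q2(X, y, 2)
        df = y_scramble(X, y, 2, n_perm=15, seed=1)
        assert len(df) == 15
        assert df["q2"].mean() < real_q2
        assert df["q2"].mean() < 0.2

    def test_field_contributions_normalized(self, rng):
        X = rng.normal(size=(10, 6))
        coef = rng.normal(size=6)
        labels = ["S"] * 3 + ["E"] * 3
        contrib = field_contributions(coef, X, labels)
        assert set(contrib) == {"S", "E"}
        assert sum(contrib.values()) == pytest.approx(1.0)


class TestColumnFilter:
    def test_low_range_columns_removed(self):
        # column 0 range 1.5 (dropped); column 1 range 3.0 (kept);
        # a range of exactly 2.0 would be kept (>= convention)
        X = np.array([[0.0, 0.0], [1.0, 3.0], [1.5, 0.5]])
        Xf, kept, labels = column_filter(X, ["S", "E"], threshold=2.0)
        assert kept.tolist() == [1]
        assert Xf.shape == (3, 1)
        assert list(labels) == ["E"]

    def test_all_removed_raises(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            column_filter(X, ["S", "E"], threshold=2.0)


class TestFieldPLS:
    def test_recovery_on_planted_series(self, fitted_qsar):
        _, spec, res = fitted_qsar
        assert res.q2 > 0.6
        assert res.r2 > 0.9
        assert res.reliable

    def test_planted_signs_recovered(self, qsar_series, fitted_qsar):
        _, truth = qsar_series
        fm, spec, res = fitted_qsar
        npts = truth["grid"].n_points
        names = fm.field_names
        coef_full = np.zeros(npts * len(names))
        coef_full[spec.kept_columns] = res.params
        for e in truth["effects"]:
            idx = names.index(e["field"]) * npts + e["column"]
            assert idx in set(spec.kept_columns.tolist())
            assert np.sign(coef_full[idx]) == np.sign(e["weight"])

    def test_summary_mentions_key_statistics(self, fitted_qsar):
        _, _, res = fitted_qsar
        text = res.summary()
        assert "q2" in text and "SEP" in text and "SEE" in text

    def test_save_load_predict_round_trip(self, tmp_path, fitted_qsar):
        fm, spec, res = fitted_qsar
        p = tmp_path / "model.json"
        res.save(p)
        payload = load_model(p)
        yhat = predict_with_payload(payload, fm)
        assert np.allclose(yhat, res.predict_field_matrix(fm), atol=1e-9)
        # payload is valid JSON with the fitted statistics
        raw = json.loads(p.read_text())
        assert raw["stats"]["q2"] == pytest.approx(res.q2)

    def test_external_validation_consistency(self, fitted_qsar, qsar_series):
        mols, _ = qsar_series
        _, spec, res = fitted_qsar
        yhat = res.predict(spec.X)
        out = res.external_validation([m.activity for m in mols], yhat)
        # internal predictions scored externally must beat the null model
        assert out["r2_pred"] > 0.9

    def test_contours_have_both_levels(self, fitted_qsar):
        _, _, res = fitted_qsar
        cf = res.contour_field()
        table = qsar.contours_to_dataframe(cf)
        assert {"favored", "disfavored"} <= set(table["polarity"])
        assert set(table["field"]) <= set(cf.values)
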