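"""NIPALS PLS2: algebraic identities, oracles, CV, validation metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from cryoextender import reference
from cryoextender.components import COMPONENT_ORDER
from cryoextender.pls import (
    NIPALSPLS,
    fit_nipals,
    jackknife_coefficients,
    jackknife_cv,
    loading_map,
    metrics,
    predict_from_equation,
)

X_COLS = list(COMPONENT_ORDER)
Y_COLS = ["tm", "pm"]


def _random_instance(rng, n=50, p=6, m=2, noise=0.3):
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + noise * rng.normal(size=(n, m))
    return X, Y


class TestNIPALSAlgebra:
    def test_full_component_pls_equals_ols(self, rng):
        """With A = rank(X), PLS predictions coincide with least squares."""
        for _ in range(5):
            X, Y = _random_instance(rng)
            model = NIPALSPLS(n_components=X.shape[1]).fit(X, Y)
            ones = np.ones((len(X), 1))
            Xd = np.hstack([ones, X])
            beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
            np.testing.assert_allclose(model.predict(X), Xd @ beta, atol=1e-8)

    def test_score_orthogonality(self, rng):
        X, Y = _random_instance(rng, n=80, p=8)
        T = NIPALSPLS(n_components=5).fit(X, Y).T_
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms) - np.eye(5)
        assert np.max(np.abs(off)) < 1e-8

    def test_coefficient_and_score_routes_agree(self, rng):
        """Back-transformed (B, intercept) reproduce the scaled-space
        score route to 1e-10."""
        X, Y = _random_instance(rng)
        m = NIPALSPLS(n_components=3).fit(X, Y)
        via_b = m.predict(X)
        T = m.transform(X)
        via_scores = m.y_mean_ + (T @ m.C_.T) * m.y_std_
        np.testing.assert_allclose(via_b, via_scores, atol=1e-10)

    def test_rank_one_single_component_perfect_fit(self, rng):
        t = rng.normal(size=40)
        X = np.outer(t, rng.normal(size=5))
        y = 2.0 * t
        m = NIPALSPLS(n_components=1).fit(X, y)
        assert metrics(y, m.predict(X)[:, 0]).r2 == pytest.approx(1.0, abs=1e-10)

    def test_cross_check_against_sklearn(self, rng):
        X, Y = _random_instance(rng, n=60, p=8)
        for A in (1, 2, 3):
            ours = NIPALSPLS(n_components=A).fit(X, Y)
            sk = PLSRegression(n_components=A, tol=1e-12).fit(X, Y)
            # sklearn's looser convergence check leaves ~1e-5 discrepancy
            np.testing.assert_allclose(
                ours.predict(X), sk.predict(X), atol=1e-4
            )

    def test_zero_variance_column_named(self, rng):
        X, Y = _random_instance(rng)
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="2"):
            NIPALSPLS(n_components=2).fit(X, Y)

    def test_too_many_components_rejected(self, rng):
        X, Y = _random_instance(rng, n=20, p=4)
        with pytest.raises(ValueError, match="exceeds rank"):
            NIPALSPLS(n_components=5).fit(X, Y)

    def test_noisefree_recovery_of_reference_equations(self, noisefree_table):
        """Full-component PLS on noise-free study-structured data returns
        the generator's coefficients to >= 6 significant digits."""
        m = fit_nipals(noisefree_table, X_COLS, Y_COLS, n_components=12)
        for j, resp in enumerate(Y_COLS):
            truth = np.array([reference.COEFFICIENTS[resp][c] for c in X_COLS])
            np.testing.assert_allclose(m.coef_[:, j], truth, rtol=1e-6)
            assert m.intercept_[j] == pytest.approx(reference.INTERCEPT[resp], rel=1e-6)

    def test_calibration_r2_at_default_noise(self, default_table):
        m = fit_nipals(default_table, X_COLS, Y_COLS, n_components=3)
        pred = m.predict(default_table[X_COLS].to_numpy(float))
        r2 = metrics(default_table["tm"], pred[:, 0]).r2
        assert 0.5 <= r2 <= 0.95


class TestPredictFromEquation:
    def test_reference_tm_at_best_formulation(self):
        rows = pd.DataFrame([reference.BEST_TM_FORMULATION])
        pred = predict_from_equation(
            reference.INTERCEPT["tm"], reference.COEFFICIENTS["tm"], rows
        )[0]
        assert pred == pytest.approx(reference.BEST_TM_PREDICTED, abs=0.15)

    def test_reference_pm_at_best_formulation(self):
        rows = pd.DataFrame([reference.BEST_PM_FORMULATION])
        pred = predict_from_equation(
            reference.INTERCEPT["pm"], reference.COEFFICIENTS["pm"], rows
        )[0]
        assert pred == pytest.approx(reference.BEST_PM_PREDICTED, abs=0.15)

    def test_zero_concentrations_return_intercept(self):
        rows = pd.DataFrame([{c: 0.0 for c in X_COLS}])
        pred = predict_from_equation(
            reference.INTERCEPT["tm"], reference.COEFFICIENTS["tm"], rows
        )[0]
        assert pred == 72.329

    def test_missing_component_rejected(self):
        rows = pd.DataFrame([{c: 0.0 for c in X_COLS[:-1]}])
        with pytest.raises(ValueError, match="ethylene_glycol"):
            predict_from_equation(0.0, reference.COEFFICIENTS["tm"], rows)


class TestMetrics:
    def test_perfect_prediction(self):
        out = metrics([1, 2, 3], [1, 2, 3])
        assert (out.r2, out.rmse, out.mape) == (1.0, 0.0, 0.0)
        assert np.isinf(out.rpd)

    def test_hand_computed_example(self):
        out = metrics([10, 20, 30], [20, 20, 20])
        assert out.rmse == pytest.approx(np.sqrt(200 / 3))
        assert out.mape == pytest.approx(100 * (1 + 0 + 1 / 3) / 3)

    def test_rpd_identity(self, rng):
        M = rng.normal(50, 10, size=30)
        P = M + rng.normal(0, 3, size=30)
        out = metrics(M, P)
        assert out.rpd == pytest.approx(np.std(M, ddof=1) / out.rmse, rel=1e-12)

    def test_zero_measured_excluded_from_mape(self):
        out = metrics([0.0, 10.0, 20.0], [1.0, 11.0, 19.0])
        assert out.n_mape_excluded == 1
        assert out.mape == pytest.approx(100 * (0.1 + 0.05) / 2)

    def test_printed_variant_differs(self, rng):
        M = rng.normal(50, 10, size=30)
        P = M + rng.normal(0, 5, size=30)
        assert metrics(M, P).r2 != metrics(M, P, printed_variant=True).r2

    def test_constant_measured_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            metrics([5.0, 5.0], [4.0, 6.0])


class TestJackknife:
    def test_q2_near_one_for_noisefree_one_component(self, rng):
        t = rng.normal(size=60)
        X = np.outer(t, rng.normal(size=5)) + 1e-6 * rng.normal(size=(60, 5))
        tbl = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
        tbl["y"] = 3 * t
        tbl["bull_id"] = np.tile([f"B{i}" for i in range(6)], 10)
        cv, rec = jackknife_cv(tbl, [f"x{i}" for i in range(5)], ["y"], max_components=3)
        assert cv["q2"].iloc[0] > 0.999
        assert rec == 1

    def test_q2_nonpositive_for_pure_noise(self, rng):
        tbl = pd.DataFrame(rng.normal(size=(80, 5)), columns=[f"x{i}" for i in range(5)])
        tbl["y"] = rng.normal(size=80)
        tbl["bull_id"] = np.tile([f"B{i}" for i in range(8)], 10)
        cv, _ = jackknife_cv(tbl, [f"x{i}" for i in range(5)], ["y"], max_components=4)
        assert (cv["q2"] <= 0.05).all()

    def test_recommended_components_on_default_fixture(self, default_table):
        _, rec = jackknife_cv(default_table, X_COLS, Y_COLS, max_components=5)
        assert rec <= 3

    def test_single_group_rejected(self, rng):
        tbl = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "y"])
        tbl["bull_id"] = "B1"
        with pytest.raises(ValueError, match="two groups"):
            jackknife_cv(tbl, ["a", "b"], ["y"])

    def test_jackknife_intervals_cover_truth(self, default_table):
        """True generator coefficients fall inside the delete-one-bull
        95% intervals for the large majority of coefficients."""
        jk = jackknife_coefficients(
            default_table, X_COLS, Y_COLS, n_components=12
        )
        covered = 0
        total = 0
        for j, resp in enumerate(Y_COLS):
            truth = np.array([reference.COEFFICIENTS[resp][c] for c in X_COLS])
            covered += int(((jk["lower"][:, j] <= truth) & (truth <= jk["upper"][:, j])).sum())
            total += len(truth)
        assert covered / total >= 0.75  # single-table check; 20-seed sweep elsewhere


class TestLoadingMap:
    def test_single_driver_dominates_first_weight(self, rng):
        n = 200
        x0 = rng.normal(size=n)
        X = np.column_stack([x0] + [0.05 * rng.normal(size=n) for _ in range(4)])
        Y = np.column_stack([2 * x0, 3 * x0]) + 0.05 * rng.normal(size=(n, 2))
        m = NIPALSPLS(n_components=2).fit(X, Y)
        wstar, c = loading_map(m)
        assert np.argmax(np.abs(wstar[:, 0])) == 0
        assert np.sign(wstar[0, 0]) == np.sign(c[0, 0]) == np.sign(c[1, 0])

    def test_requires_two_components(self, rng):
        X, Y = _random_instance(rng)
        m = NIPALSPLS(n_components=1).fit(X, Y)
        with pytest.raises(ValueError):
            loading_map(m)

    def test_coordinates_finite(self, default_table):
        m = fit_nipals(default_table, X_COLS, Y_COLS, n_components=3)
        wstar, c = loading_map(m)
        assert np.isfinite(wstar).all() and np.isfinite(c).all()
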