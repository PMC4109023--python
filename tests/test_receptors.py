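"""PLS regression, β-weight matrices, confusion reports, cross-validation."""

import warnings

import numpy as np
import pandas as pd
import pytest

import thromboquant as tq
from thromboquant.receptors import (
    confusion,
    crossval,
    fit_pls,
    predict,
    predict_type,
    receptor_beta,
    refit_lowshear,
    subtraction_heatmap,
)


def naive_nipals(X, y, n_components):
    """Textbook PLS1 NIPALS, written independently: explicit deflation loop,
    prediction via accumulated scores rather than a coefficient vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = X.mean(axis=0), y.mean()
    E, f = X - xm, y - ym
    pred = np.full(len(y), ym)
    Ws, Ps, Qs = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.sqrt(w @ w)
        t = E @ w
        p = E.T @ t / (t @ t)
        q = (f @ t) / (t @ t)
        pred = pred + q * t
        E = E - np.outer(t, p)
        f = f - q * t
        Ws.append(w), Ps.append(p), Qs.append(q)
    return pred, np.array(Ws).T, np.array(Ps).T, np.array(Qs)


class TestFitPLS:
    def test_full_component_pls_equals_ols(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X = rng.normal(size=(20, 6))
            y = rng.normal(size=20)
            m = fit_pls(X, y, 6)
            ols = np.linalg.lstsq(np.column_stack([np.ones(20), X]), y, rcond=None)[0]
            assert np.allclose(m.coef, ols[1:], atol=1e-8)
            assert m.intercept == pytest.approx(ols[0], abs=1e-8)

    def test_single_informative_column_one_component(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=30), rng.normal(size=30) * 1e-9])
        y = 2.0 * X[:, 0] + 1.0
        m = fit_pls(X, y, 1)
        assert np.corrcoef(predict(m, X), y)[0, 1] == pytest.approx(1.0)

    def test_matches_independent_nipals_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        for nc in (1, 2, 3):
            m = fit_pls(X, y, nc)
            oracle_pred, W, P, Q = naive_nipals(X, y, nc)
            assert np.allclose(predict(m, X), oracle_pred, atol=1e-10)
            assert np.allclose(np.abs(m.weights), np.abs(W), atol=1e-10)

    def test_matches_sklearn(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 7))
        y = rng.normal(size=25)
        for nc in (1, 2, 4):
            sk = PLSRegression(n_components=nc, scale=False).fit(X, y)
            m = fit_pls(X, y, nc)
            assert np.allclose(sk.predict(X).ravel(), predict(m, X), atol=1e-10)

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        y = X["a"].to_numpy()
        with pytest.warns(UserWarning, match="zero-variance"):
            m = fit_pls(X, y, 1)
        assert m.dropped_columns == ["b"]
        assert m.columns == ["a"]

    def test_excess_components_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, rng.normal(size=10), 4)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        m1 = fit_pls(X, y, 2)
        m2 = fit_pls(X, 3.5 * y, 2)
        assert np.allclose(3.5 * m1.coef, m2.coef)

    def test_variance_explained_sums_below_one(self):
        rng = np.random.default_rng(8)
        m = fit_pls(rng.normal(size=(30, 5)), rng.normal(size=30), 3)
        assert ((m.x_variance_explained >= 0) & (m.x_variance_explained <= 1)).all()
        assert m.x_variance_explained.sum() <= 1 + 1e-12


class TestPrediction:
    def test_rounding_and_clamping(self):
        m = fit_pls(np.array([[1.0], [2.0], [3.0]]), np.array([1.0, 2.0, 3.0]), 1)
        X = np.array([[1.4], [2.5], [3.9], [0.2]])
        # continuous predictions equal the x value here (identity fit)
        assert predict_type(m, X).tolist() == [1, 3, 3, 1]

    def test_noise_free_planted_design_zero_misassignments(self):
        truth = tq.planted_receptor_truth(seed=1, noise_sd=0.0)
        d = tq.gen_receptor_design(truth, 52)
        rank = np.linalg.matrix_rank(d.assignment.to_numpy() - d.assignment.to_numpy().mean(axis=0))
        m = fit_pls(d.assignment, d.response, rank)
        true_types = np.clip(np.floor(d.response + 0.5), 1, 3).astype(int)
        rep = confusion(true_types, predict_type(m, d.assignment))
        assert rep.misassigned == 0

    def test_column_mismatch_rejected(self):
        m = fit_pls(pd.DataFrame({"a": [1.0, 2.0, 4.0]}), np.array([1.0, 2.0, 4.0]), 1)
        with pytest.raises(ValueError, match="column"):
            predict(m, pd.DataFrame({"z": [1.0]}))


class TestConfusion:
    def test_identical_vectors(self):
        rep = confusion([1, 2, 3, 2], [1, 2, 3, 2])
        assert rep.misassigned == 0
        assert np.trace(rep.matrix.to_numpy()) == 4

    def test_two_swaps_counted(self):
        rep = confusion([1, 1, 2, 2, 3, 3], [1, 2, 2, 3, 3, 3])
        assert rep.misassigned == 2
        assert rep.per_class_errors.tolist() == [1, 1, 0]

    def test_random_labels_accuracy_one_third(self):
        rng = np.random.default_rng(9)
        accs = []
        for _ in range(300):
            t = np.repeat([1, 2, 3], 10)
            p = rng.integers(1, 4, size=30)
            rep = confusion(t, p)
            accs.append(np.trace(rep.matrix.to_numpy()) / 30)
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.02)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="1, 2, 3"):
            confusion([1, 4], [1, 2])


class TestCrossval:
    def test_noise_free_design_zero_cv_misassignments(self):
        truth = tq.planted_receptor_truth(seed=2, noise_sd=0.0)
        d = tq.gen_receptor_design(truth, 52)
        rank = np.linalg.matrix_rank(d.assignment.to_numpy() - d.assignment.to_numpy().mean(axis=0))
        rep, preds = crossval(d.assignment, d.response, rank)
        true_types = np.clip(np.floor(d.response + 0.5), 1, 3).astype(int)
        assert (preds == true_types).all()
        assert rep.source == "cross-validation"

    def test_cv_differs_from_resubstitution_on_noisy_data(self):
        truth = tq.planted_receptor_truth(seed=3, noise_sd=0.3)
        d = tq.gen_receptor_design(truth, 40)
        m = fit_pls(d.assignment, d.response, 3)
        resub = predict_type(m, d.assignment)
        _, cv_preds = crossval(d.assignment, d.response, 3)
        assert (resub != cv_preds).any()

    def test_planted_noise_low_misassignment_rate(self):
        rates = []
        for seed in range(20):
            truth = tq.planted_receptor_truth(seed=seed, noise_sd=0.1)
            d = tq.gen_receptor_design(truth, 52)
            true_types = np.clip(
                np.floor(np.clip(truth.beta_true[0] + d.assignment.to_numpy() @ truth.beta_true[1:], 1, 3) + 0.5),
                1, 3,
            ).astype(int)
            _, preds = crossval(d.assignment, d.response, 3)
            rates.append(np.mean(preds != true_types))
        assert np.mean(rates) < 0.15

    def test_minimum_size(self):
        with pytest.raises(ValueError, match="at least 3"):
            crossval(np.eye(2), np.array([1.0, 2.0]), 1)


class TestReceptorBeta:
    def test_dominant_planted_receptor_recovered_largest(self):
        beta = np.zeros(10)
        beta[0] = 1.5
        beta[2] = 0.9  # GPVI-like dominant column
        beta[1], beta[4] = 0.2, 0.1
        truth = tq.PlantedReceptorTruth(assignment_rows=None, beta_true=beta, noise_sd=0.0, seed=4)
        d = tq.gen_receptor_design(truth, 52)
        bwm, _rep, _m = receptor_beta(d.assignment, d.response, 3)
        assert bwm.weights.idxmax() == "GPVI"

    def test_never_engaged_receptor_dropped(self):
        truth = tq.planted_receptor_truth(seed=5, noise_sd=0.0)
        d = tq.gen_receptor_design(truth, 30)
        A = d.assignment.copy()
        A["CD36"] = 0
        A = A[A.sum(axis=1) > 0]  # keep surfaces still engaging something
        y = np.clip(truth.beta_true[0] + A.to_numpy() @ truth.beta_true[1:], 1, 3)
        with pytest.warns(UserWarning, match="zero-variance"):
            bwm, _rep, _m = receptor_beta(A, y, 3)
        assert "CD36" not in bwm.weights.index

    def test_rank_deficiency_suggests_component_count(self):
        A = pd.DataFrame(
            {"r1": [1, 0, 1, 0], "r2": [1, 0, 1, 0], "r3": [0, 1, 0, 1]}
        )
        with pytest.raises(ValueError, match="n_components=1"):
            receptor_beta(A, np.array([1.0, 2.0, 1.0, 2.0]), 3)

    def test_nonbinary_assignment_rejected(self):
        A = pd.DataFrame({"r1": [1, 2], "r2": [1, 0]})
        with pytest.raises(ValueError, match="binary"):
            receptor_beta(A, np.array([1.0, 2.0]), 1)


class TestRefitLowShear:
    def test_exclude_zero_weight_receptor_leaves_weights_unchanged(self):
        beta = np.array([1.5, 0.4, 0.3, 0.0, 0.2, 0.1, 0.25, 0.3, 0.15, 0.1])
        truth = tq.PlantedReceptorTruth(assignment_rows=None, beta_true=beta, noise_sd=0.0, seed=6)
        d = tq.gen_receptor_design(truth, 60)
        rank = np.linalg.matrix_rank(d.assignment.to_numpy() - d.assignment.to_numpy().mean(axis=0))
        full, _r, _m = receptor_beta(d.assignment, d.response, rank, shear="high")
        # CLEC-2 column has planted weight exactly 0
        excl, _r2, _m2 = refit_lowshear(
            d.assignment, d.response, n_components=rank - 1, exclude_receptor="CLEC-2"
        )
        kept = [r for r in full.weights.index if r != "CLEC-2"]
        assert np.allclose(full.weights[kept], excl.weights[kept], atol=1e-6)
        assert abs(full.weights["CLEC-2"]) < 1e-8

    def test_separate_scaled_refit_on_same_data_identical(self):
        truth = tq.planted_receptor_truth(seed=7)
        d = tq.gen_receptor_design(truth, 40)
        high, _r, _m = receptor_beta(d.assignment, d.response, 2, shear="high")
        low, _r2, _m2 = refit_lowshear(d.assignment.copy(), d.response.copy(), n_components=2)
        assert np.allclose(high.weights, low.weights)
        assert high.intercept == pytest.approx(low.intercept)

    def test_unknown_receptor_rejected(self):
        truth = tq.planted_receptor_truth(seed=8)
        d = tq.gen_receptor_design(truth, 20)
        with pytest.raises(ValueError, match="unknown receptor"):
            refit_lowshear(d.assignment, d.response, exclude_receptor="GPXX")

    def test_decoupled_receptor_weight_near_zero(self):
        # response built without any GPIb contribution: its weight must vanish
        beta = np.array([1.4, 0.0, 0.35, 0.3, 0.2, 0.1, 0.3, 0.25, 0.1, 0.05])
        truth = tq.PlantedReceptorTruth(assignment_rows=None, beta_true=beta, noise_sd=0.05, seed=9)
        d = tq.gen_receptor_design(truth, 60)
        rank = np.linalg.matrix_rank(d.assignment.to_numpy() - d.assignment.to_numpy().mean(axis=0))
        bwm, _r, _m = receptor_beta(d.assignment, d.response, rank)
        assert abs(bwm.weights["GPIb-V-IX"]) < 0.1


class TestSubtractionHeatmap:
    @staticmethod
    def make_reps(mat, sd, n, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for s in mat.index:
            for c in mat.columns:
                for r in range(n):
                    rows.append((s, c, r + 1, mat.loc[s, c] + rng.normal(0, sd)))
        return pd.DataFrame(rows, columns=["surface", "parameter", "run", "value"])

    def test_equal_conditions_no_signal(self):
        mat = pd.DataFrame(5.0, index=["s1", "s2"], columns=["p1", "p2"])
        ra = self.make_reps(mat, 0.5, 4, 1)
        rb = self.make_reps(mat, 0.5, 4, 2)
        ma = ra.groupby(["surface", "parameter"])["value"].mean().unstack()
        mb = rb.groupby(["surface", "parameter"])["value"].mean().unstack()
        diff, p, sig = subtraction_heatmap(ma, mb, ra, rb)
        assert np.allclose(diff, ma - mb)
        assert (p > 0.001).all().all()

    def test_single_cell_matches_closed_form_t(self):
        from scipy import stats

        va, vb = np.array([4.0, 6.0]), np.array([8.0, 12.0])
        mat_a = pd.DataFrame({"p": [va.mean()]}, index=["s"])
        mat_b = pd.DataFrame({"p": [vb.mean()]}, index=["s"])
        ra = pd.DataFrame({"surface": "s", "parameter": "p", "run": [1, 2], "value": va})
        rb = pd.DataFrame({"surface": "s", "parameter": "p", "run": [1, 2], "value": vb})
        _diff, p, _sig = subtraction_heatmap(mat_a, mat_b, ra, rb)
        sp2 = (va.var(ddof=1) + vb.var(ddof=1)) / 2
        t = (va.mean() - vb.mean()) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        p_hand = 2 * stats.t.sf(abs(t), 2)
        assert p.loc["s", "p"] == pytest.approx(p_hand, abs=1e-12)

    def test_layout_mismatch_rejected(self):
        a = pd.DataFrame(1.0, index=["s1"], columns=["p1"])
        b = pd.DataFrame(1.0, index=["s2"], columns=["p1"])
        with pytest.raises(ValueError, match="layout"):
            subtraction_heatmap(a, b, None, None)

    def test_planted_shift_detected(self):
        mat = pd.DataFrame(5.0, index=[f"s{i}" for i in range(4)], columns=["p1", "p2"])
        shifted = mat.copy()
        shifted.loc["s0", "p1"] += 2.0  # +2 s.d. at sd=1, n=6
        hits = 0
        for seed in range(30):
            ra = self.make_reps(shifted, 1.0, 6, 100 + seed)
            rb = self.make_reps(mat, 1.0, 6, 200 + seed)
            ma = ra.groupby(["surface", "parameter"])["value"].mean().unstack()
            mb = rb.groupby(["surface", "parameter"])["value"].mean().unstack()
            _d, _p, sig = subtraction_heatmap(ma, mb, ra, rb)
            hits += bool(sig.loc["s0", "p1"])
        assert hits >= 24  # ~90% power for a 2-s.d. shift at n=6 per side
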