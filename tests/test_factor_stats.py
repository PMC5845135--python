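"""Factor regression: selection, inference calibration, deviation analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from footshape import factor_stats as fs
from footshape import shape_model as sm


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


class TestForwardSelection:
    def test_planted_pcs_recovered(self, rng):
        """High-SNR factors built from PCs {1,3,5} select exactly that set."""
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            n = 248
            W = r.standard_normal((n, 20)) * np.linspace(3, 0.5, 20)
            F = np.column_stack(
                [
                    W[:, 1] + 0.1 * r.standard_normal(n),
                    0.8 * W[:, 3] + 0.1 * r.standard_normal(n),
                    0.5 * W[:, 5] + 0.1 * r.standard_normal(n),
                ]
            )
            if sorted(fs.forward_select_pcs(W, F)) == [1, 3, 5]:
                hits += 1
        assert hits >= 18

    def test_pure_noise_selects_nothing(self, rng):
        n = 248
        W = rng.standard_normal((n, 30))
        F = rng.standard_normal((n, 5))
        assert fs.forward_select_pcs(W, F) == []

    def test_bic_trace_strictly_decreasing(self, rng):
        n = 200
        W = rng.standard_normal((n, 10))
        F = np.column_stack([W[:, 2] + 0.2 * rng.standard_normal(n)])
        selected, trace = fs.forward_select_pcs(W, F, return_trace=True)
        assert selected  # the planted signal is found
        assert np.all(np.diff(trace) < 0)


class TestFactorModelFit:
    def test_noise_free_exact_recovery(self, rng):
        n, k, m = 60, 4, 3
        W = rng.standard_normal((n, k))
        B = rng.standard_normal((k + 1, m))
        F = B[0] + W @ B[1:]
        model = fs.fit_factor_model(W, pd.DataFrame(F, columns=list("abc")))
        np.testing.assert_allclose(model.coefficients, B, atol=1e-8)
        assert np.all(model.r_squared.to_numpy() > 1.0 - 1e-10)

    def test_confidence_interval_coverage(self):
        """95% CIs built from the fitted model cover planted coefficients
        at the nominal rate (coverage simulation, coefficients pooled)."""
        n, k = 80, 3
        b_true = np.array([0.5, -1.0, 0.25])
        reps = 200
        base = np.random.default_rng(2024)
        X = base.standard_normal((n, k))
        Xd = np.hstack([np.ones((n, 1)), X])
        xtx_inv_diag = np.diag(np.linalg.inv(Xd.T @ Xd))[1:]
        tcrit = stats.t.ppf(0.975, n - k - 1)
        covered, total = 0, 0
        for rep in range(reps):
            r = np.random.default_rng(5000 + rep)
            y = X @ b_true + r.standard_normal(n)
            model = fs.fit_factor_model(X, pd.DataFrame({"y": y}))
            b_hat = model.coefficients[1:, 0]
            half = tcrit * model.residual_sds[0] * np.sqrt(xtx_inv_diag)
            covered += int(np.sum(np.abs(b_hat - b_true) <= half))
            total += k
        assert 0.93 <= covered / total <= 0.97

    def test_independent_factor_r2_matches_null_distribution(self, rng):
        """R^2 of a factor unrelated to the scores follows Beta(k/2,(n-k-1)/2)."""
        n, k = 248, 6
        r2s = []
        for rep in range(200):
            r = np.random.default_rng(7000 + rep)
            W = r.standard_normal((n, k))
            F = pd.DataFrame({"f": r.standard_normal(n)})
            r2s.append(fs.fit_factor_model(W, F).r_squared["f"])
        null = stats.beta(k / 2, (n - k - 1) / 2)
        assert np.mean(r2s) == pytest.approx(null.mean(), abs=0.01)
        assert np.mean(np.asarray(r2s) < null.ppf(0.95)) >= 0.90

    def test_rank_deficiency_reported(self, rng):
        W = rng.standard_normal((50, 2))
        W = np.column_stack([W, W[:, 0]])  # duplicate column
        with pytest.raises(ValueError, match="collinear"):
            fs.fit_factor_model(W, pd.DataFrame({"f": rng.standard_normal(50)}))

    def test_r2_monotone_in_nested_models(self, cohort_model, cohort):
        _, subjects, scans = cohort
        from footshape.cli_report import _factor_table

        F = _factor_table(subjects, scans)
        k_all = min(30, cohort_model.n_components)
        full = fs.fit_factor_model(cohort_model.scores[:, :k_all], F)
        sub = fs.fit_factor_model(cohort_model.scores[:, :6], F)
        assert np.all(
            full.r_squared.to_numpy() >= sub.r_squared.to_numpy() - 1e-12
        )


class TestPower:
    def test_null_power_is_alpha(self):
        assert fs.posthoc_power(0.0, 100, 6, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_n_and_r2(self):
        p = [fs.posthoc_power(0.2, n, 6) for n in (30, 60, 120, 240)]
        assert np.all(np.diff(p) > 0)
        p = [fs.posthoc_power(r2, 100, 6) for r2 in (0.05, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(p) > 0)

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            fs.posthoc_power(1.0, 100, 6)
        with pytest.raises(ValueError):
            fs.posthoc_power(-0.1, 100, 6)

    def test_matches_monte_carlo(self):
        """Noncentral-F analytic power vs a direct simulation oracle."""
        r2, n, k, reps = 0.15, 100, 6, 20000
        rng = np.random.default_rng(99)
        lam = n * r2 / (1 - r2)
        X = rng.standard_normal((n, k))
        mu_dir = X[:, 0] - X[:, 0].mean()
        mu = mu_dir * np.sqrt(lam) / np.linalg.norm(mu_dir)
        Q, _ = np.linalg.qr(np.hstack([np.ones((n, 1)), X]))
        ones = np.ones(n) / np.sqrt(n)
        Y = rng.standard_normal((reps, n)) + mu
        rss_full = np.einsum("ij,ij->i", Y - (Y @ Q) @ Q.T, Y - (Y @ Q) @ Q.T)
        resid0 = Y - np.outer(Y @ ones, ones)
        rss_null = np.einsum("ij,ij->i", resid0, resid0)
        Fstat = ((rss_null - rss_full) / k) / (rss_full / (n - k - 1))
        crit = stats.f.isf(0.05, k, n - k - 1)
        mc = float(np.mean(Fstat > crit))
        assert fs.posthoc_power(r2, n, k) == pytest.approx(mc, abs=0.01)


class TestCorrelations:
    def test_exact_copy(self, rng):
        w = rng.standard_normal(100)
        out = fs.pc_factor_correlations(w[:, None], pd.DataFrame({"f": w}))
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-10
        assert bool(out.loc[0, "significant"])

    def test_affine_invariance(self, rng):
        w = rng.standard_normal(80)
        f = 0.6 * w + rng.standard_normal(80)
        a = fs.pc_factor_correlations(w[:, None], pd.DataFrame({"f": f}))
        b = fs.pc_factor_correlations(
            (5 * w + 3)[:, None], pd.DataFrame({"f": -2 * f + 7})
        )
        assert abs(b.loc[0, "rho"]) == pytest.approx(abs(a.loc[0, "rho"]), abs=1e-12)
        assert b.loc[0, "p"] == pytest.approx(a.loc[0, "p"], rel=1e-9)

    def test_constant_column_rejected(self, rng):
        w = rng.standard_normal(50)
        with pytest.raises(ValueError):
            fs.pc_factor_correlations(w[:, None], pd.DataFrame({"f": np.ones(50)}))

    def test_spearman_option(self, rng):
        w = rng.standard_normal(60)
        f = np.exp(w)  # monotone, nonlinear
        sp = fs.pc_factor_correlations(w[:, None], pd.DataFrame({"f": f}), "spearman")
        assert sp.loc[0, "rho"] == pytest.approx(1.0)


class TestDeviationField:
    def test_identical_shapes_zero(self, rng):
        a = rng.standard_normal(60)
        dev = fs.deviation_field(a, a)
        assert not dev.values.any()

    def test_uniform_offset(self, rng):
        a = rng.standard_normal(60).reshape(-1, 3)
        b = a + [1.0, 0.0, 0.0]
        dev = fs.deviation_field(a.reshape(-1), b.reshape(-1))
        np.testing.assert_allclose(dev.values, 1.0, atol=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(60), rng.standard_normal(60)
        np.testing.assert_array_equal(
            fs.deviation_field(a, b).values, fs.deviation_field(b, a).values
        )

    def test_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fs.deviation_field(rng.standard_normal(60), rng.standard_normal(63))


class TestDeviationRegression:
    def test_planted_bmi_effect_recovered(self, rng):
        n_subj, V = 62, 400
        bmi = rng.normal(24, 3.5, n_subj)
        pattern = np.abs(rng.standard_normal(V))
        fields = (
            np.outer((bmi - bmi.mean()) / bmi.std(), pattern)
            + 0.3 * rng.standard_normal((n_subj, V))
        )
        fields = np.abs(fields)
        F = pd.DataFrame({"bmi": bmi, "age": rng.normal(40, 12, n_subj)})
        model, _ = fs.deviation_regression(fields, F)
        null95 = stats.beta(
            len(model.selected_pcs) / 2,
            (model.n_obs - len(model.selected_pcs) - 1) / 2,
        ).ppf(0.95)
        assert model.r_squared["bmi"] > null95
        assert model.p_values["bmi"] < 0.05

    def test_noise_fields_mostly_insignificant(self):
        """Study-sized null cohorts (62 subjects, 5 factors): deviation
        regression flags factors at roughly the type-I rate."""
        flags = 0
        total = 0
        for rep in range(20):
            r = np.random.default_rng(3000 + rep)
            fields = np.abs(r.standard_normal((62, 200)))
            F = pd.DataFrame(
                r.standard_normal((62, 5)), columns=list("abcde")
            )
            model, _ = fs.deviation_regression(fields, F)
            flags += int(model.significant.sum())
            total += 5
        assert flags / total <= 0.15  # near the 5% type-I expectation

    def test_zero_fields_rejected(self):
        with pytest.raises(ValueError):
            fs.deviation_regression(np.zeros((10, 50)), pd.DataFrame({"a": range(10)}))


class TestPredictShape:
    @pytest.fixture()
    def fitted(self, rng):
        n, k = 120, 3
        W = rng.standard_normal((n, k)) * [3.0, 2.0, 1.0]
        F = pd.DataFrame(
            {
                "bmi": 24 + 2.0 * W[:, 0] + 0.2 * rng.standard_normal(n),
                "age": 40 + 5.0 * W[:, 1] + 0.2 * rng.standard_normal(n),
                "inert": rng.normal(0, 1, n),
            }
        )
        X = rng.standard_normal((n, 60)) * 0.01 + W @ rng.standard_normal((k, 60))
        shape = sm.fit_pca(X, "full")
        scores = np.column_stack([sm.project(shape, x) for x in X]).T
        fmodel = fs.fit_factor_model(scores[:, :k], F, selected_pcs=[0, 1, 2])
        return fmodel, shape

    def test_zero_effect_factor_gives_identical_shapes(self, fitted):
        fmodel, shape = fitted
        # force the fitted effect of 'inert' to exactly zero: varying it
        # must leave the predicted shape at the conditional mean
        fmodel.coefficients[1:, fmodel.factor_names.index("inert")] = 0.0
        lo, hi, dev = fs.predict_shape(fmodel, shape, vary="inert")
        np.testing.assert_allclose(lo, hi, atol=1e-8)
        np.testing.assert_allclose(dev.values, 0.0, atol=1e-8)

    def test_midpoint_linearity(self, fitted):
        fmodel, shape = fitted
        lo, hi, _ = fs.predict_shape(fmodel, shape, vary="bmi", range_rule="minmax")
        row = fmodel.factor_summary.loc["bmi"]
        mid_val = (row["min"] + row["max"]) / 2.0
        lo2, hi2, _ = fs.predict_shape(
            fmodel, shape, factor_values={"bmi": mid_val}, vary="age"
        )
        # prediction is affine in the factor vector: midpoint of endpoints
        base = fmodel.factor_summary["mean"].reindex(fmodel.factor_names)
        # direct check: synthesizing at the midpoint equals the average
        w_mid_shape = (lo + hi) / 2.0
        f = base.to_numpy(dtype=float).copy()
        f[fmodel.factor_names.index("bmi")] = mid_val
        w, *_ = np.linalg.lstsq(
            fmodel.coefficients[1:].T, f - fmodel.coefficients[0], rcond=None
        )
        w_full = np.zeros(shape.n_components)
        w_full[fmodel.selected_pcs] = w
        np.testing.assert_allclose(
            sm.synthesize(shape, w_full), w_mid_shape, atol=1e-8
        )

    def test_unknown_factor_rejected(self, fitted):
        fmodel, shape = fitted
        with pytest.raises(ValueError):
            fs.predict_shape(fmodel, shape, vary="height")
        with pytest.raises(ValueError):
            fs.predict_shape(fmodel, shape, vary="bmi", range_rule="bogus")

    def test_permuting_factor_destroys_significance(self, fitted, rng):
        fmodel, _ = fitted
        # refit with a permuted bmi column: significance should vanish
        n = fmodel.n_obs
        high_p = 0
        reps = 20
        for rep in range(reps):
            r = np.random.default_rng(4000 + rep)
            W = r.standard_normal((n, 3))
            F = pd.DataFrame({"y": r.permutation(2.0 * W[:, 0])})
            m = fs.fit_factor_model(W, F)
            if m.p_values["y"] > 0.05:
                high_p += 1
        assert high_p >= reps * 0.9
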