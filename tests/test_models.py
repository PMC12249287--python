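"""Collinearity screening, logistic fits, AICc ranking, weights and averaging."""

import numpy as np
import pandas as pd
import pytest

from wolfrecol import models, simulate


@pytest.fixture
def balanced_table(rng):
    n = 40
    return pd.DataFrame(
        {
            "status": np.r_[np.ones(n // 2), np.zeros(n // 2)],
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        }
    )


class TestCollinearityScreen:
    def test_identical_columns_one_dropped(self, rng):
        x = rng.normal(size=50)
        t = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        kept = models.collinearity_screen(t)
        assert len(kept) == 2 and "c" in kept

    def test_independent_covariates_all_kept(self, rng):
        t = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
        assert models.collinearity_screen(t) == list("abcd")

    def test_constant_column_dropped_with_warning(self, rng):
        t = pd.DataFrame({"a": np.ones(30), "b": rng.normal(size=30), "c": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            kept = models.collinearity_screen(t)
        assert kept == ["b", "c"]

    def test_hub_covariate_dropped(self, rng):
        # the derived total-area covariate correlates with two others and is
        # the one removed
        g = simulate.build_grid((0, 0, 50_000, 90_000))
        cov = simulate.gen_covariates(g, seed=2)
        kept = models.collinearity_screen(cov, [c for c in cov.columns if c != "cell_id"])
        assert "forest_area" not in kept
        assert len(kept) == 5


class TestEnumerateModels:
    @pytest.mark.parametrize("p, expected", [(5, 32), (0, 1), (3, 8)])
    def test_counts(self, p, expected):
        assert len(models.enumerate_models([f"x{i}" for i in range(p)])) == expected

    def test_null_model_included(self):
        assert () in models.enumerate_models(["a", "b"])

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError):
            models.enumerate_models([f"x{i}" for i in range(21)])


class TestFitLogistic:
    def test_null_model_closed_form(self, balanced_table):
        fit = models.fit_logistic(balanced_table, ())
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(40 * np.log(0.5))
        assert fit.k == 1

    @pytest.mark.parametrize(
        "loglik, k, expected",
        [(-12.5049, 2, 29.5316), (-11.7519, 3, 30.5948)],
    )
    def test_aicc_arithmetic(self, loglik, k, expected):
        assert models.aicc_from_loglik(loglik, k, 26) == pytest.approx(expected, abs=1e-3)

    def test_aicc_exceeds_aic_and_converges_to_it(self, balanced_table):
        fit = models.fit_logistic(balanced_table, ("a",))
        assert fit.aicc > fit.aic
        big_n = models.aicc_from_loglik(-100.0, 3, 10**6)
        assert abs(big_n - (-2 * -100.0 + 6)) < 1e-4

    def test_aicc_undefined_when_saturated(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            models.aicc_from_loglik(-1.0, 5, 6)

    def test_separation_flagged(self):
        t = pd.DataFrame({"status": [0, 0, 0, 1, 1, 1], "x": [1, 2, 3, 10, 11, 12.0]})
        with pytest.warns(UserWarning, match="separation"):
            fit = models.fit_logistic(t, ("x",))
        assert fit.separation


class TestRanking:
    def make_fit(self, loglik, k, terms):
        return models.ModelFit(
            terms=terms,
            coefficients={},
            loglik=loglik,
            k=k,
            n=26,
            aic=-2 * loglik + 2 * k,
            aicc=models.aicc_from_loglik(loglik, k, 26),
        )

    def test_weight_ratio_follows_delta(self):
        # the second model's weight equals the best weight times exp(-delta/2)
        fits = [self.make_fit(-12.5049, 2, ("fc",)), self.make_fit(-11.7519, 3, ("fc", "pa"))]
        ranking = models.rank_and_weight(fits)
        delta2 = ranking.delta[1]
        assert delta2 == pytest.approx(1.0632, abs=1e-3)
        ratio = ranking.weights[1] / ranking.weights[0]
        assert 0.2020 * ratio == pytest.approx(0.1187, abs=0.0005)

    def test_single_model_weight_one(self):
        ranking = models.rank_and_weight([self.make_fit(-10, 2, ("a",))])
        assert ranking.weights[0] == 1.0

    def test_weights_normalize(self, rng):
        fits = [
            self.make_fit(float(-rng.uniform(5, 20)), int(k), (f"m{i}",))
            for i, k in enumerate(rng.integers(1, 5, size=32))
        ]
        ranking = models.rank_and_weight(fits)
        assert ranking.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(ranking.delta) >= 0).all()

    def test_loglik_shift_leaves_delta_and_weights(self, rng):
        lls = -rng.uniform(5, 20, size=8)
        fits = [self.make_fit(ll, 2, (f"m{i}",)) for i, ll in enumerate(lls)]
        shifted = [self.make_fit(ll + 7.0, 2, (f"m{i}",)) for i, ll in enumerate(lls)]
        r1, r2 = models.rank_and_weight(fits), models.rank_and_weight(shifted)
        np.testing.assert_allclose(r1.delta, r2.delta, atol=1e-9)
        np.testing.assert_allclose(r1.weights, r2.weights, atol=1e-9)

    def test_separated_fits_excluded(self):
        good = self.make_fit(-10, 2, ("a",))
        bad = self.make_fit(-1, 2, ("b",))
        bad.separation = True
        with pytest.warns(UserWarning, match="excluded"):
            ranking = models.rank_and_weight([good, bad])
        assert [f.terms for f in ranking.fits] == [("a",)]

    def test_competitor_set_is_delta_below_two(self):
        fits = [self.make_fit(ll, 2, (f"m{i}",)) for i, ll in enumerate([-10.0, -10.5, -12.0])]
        ranking = models.rank_and_weight(fits)
        assert [f.terms for f in ranking.competitors] == [("m0",), ("m1",)]


class TestAveraging:
    def ranked(self, specs):
        fits = []
        for ll, terms, coefs in specs:
            fits.append(
                models.ModelFit(
                    terms=terms,
                    coefficients=coefs,
                    loglik=ll,
                    k=len(terms) + 1,
                    n=26,
                    aic=0.0,
                    aicc=models.aicc_from_loglik(ll, len(terms) + 1, 26),
                )
            )
        return models.rank_and_weight(fits)

    def test_absent_term_shrinks_by_half_at_equal_weight(self):
        r = self.ranked(
            [
                (-10.0, ("a",), {"intercept": 0.0, "a": 1.0}),
                (-11.177536, (), {"intercept": 0.0}),  # AICc exactly equal to the first
            ]
        )
        assert r.delta[1] == pytest.approx(0.0, abs=1e-6)
        avg = models.average_models(r)
        assert avg["a"] == pytest.approx(0.5, abs=1e-6)

    def test_conditional_averaging_keeps_full_effect(self):
        r = self.ranked(
            [
                (-10.0, ("a",), {"intercept": 0.0, "a": 1.0}),
                (-11.177536, (), {"intercept": 0.0}),
            ]
        )
        avg = models.average_models(r, method="conditional")
        assert avg["a"] == pytest.approx(1.0)

    def test_single_competitor_identity(self):
        r = self.ranked(
            [
                (-10.0, ("a",), {"intercept": 0.3, "a": 1.2}),
                (-15.0, (), {"intercept": 0.0}),
            ]
        )
        assert len(r.competitors) == 1
        assert models.average_models(r) == {"intercept": 0.3, "a": 1.2}

    def test_weighted_sum_matches_hand_computation(self):
        r = self.ranked(
            [
                (-10.0, ("a",), {"intercept": 0.1, "a": 2.0}),
                (-10.2, ("b",), {"intercept": -0.1, "b": 1.0}),
                (-9.0, ("a", "b"), {"intercept": 0.0, "a": 1.0, "b": 0.5}),
            ]
        )
        w = r.weights[: len(r.competitors)]
        w = w / w.sum()
        avg = models.average_models(r)
        expected_a = w[0] * 2.0 + w[2] * 1.0
        assert avg["a"] == pytest.approx(expected_a, abs=1e-12)


class TestParameterRecovery:
    def test_full_model_recovers_truth_within_3se(self, rng):
        # the generating logistic model refit on its own draws stays within
        # 3 standard errors of truth in >= 95% of replicates
        import statsmodels.api as sm

        beta = {"intercept": -0.3, "a": 0.8, "b": -0.5}
        ok = 0
        reps = 60
        for r in range(reps):
            cov = pd.DataFrame(
                {
                    "cell_id": range(200),
                    "a": rng.normal(size=200),
                    "b": rng.normal(size=200),
                }
            )
            for c in ("a", "b"):
                cov[c] = (cov[c] - cov[c].mean()) / cov[c].std()
            table = simulate.gen_status_table(cov, beta, seed=1000 + r)
            fit = models.fit_logistic(table, ("a", "b"))
            X = sm.add_constant(table[["a", "b"]])
            se = sm.GLM(table["status"], X, family=sm.families.Binomial()).fit().bse
            truth = np.array([beta["intercept"], beta["a"], beta["b"]])
            est = np.array([fit.coefficients["intercept"], fit.coefficients["a"], fit.coefficients["b"]])
            if (np.abs(est - truth) <= 3 * se.to_numpy()).all():
                ok += 1
        assert ok / reps >= 0.95
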