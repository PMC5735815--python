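"""MI engine: proper draws, chained equations, Rubin pooling and FMI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from proxymi import (
    CohortParams,
    ImputationModelSpec,
    chained_impute,
    generate_cohort,
    pool_rubin,
    proper_normal_linear_draw,
)
from proxymi.linmod import SingularDesignError, TooFewCasesError, ols


class TestProperDraw:
    def test_no_missing_cells_returns_data_unchanged(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = rng.standard_normal(50)
        out = proper_normal_linear_draw(X, y, np.ones(50, bool), rng)
        np.testing.assert_array_equal(out, y)

    def test_noiseless_data_imputes_fitted_values(self):
        # y exactly linear in X: RSS = 0, so the posterior draws degenerate
        # and imputations equal the OLS fitted values
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        X = np.column_stack([np.ones(100), x])
        y = 2.0 + 3.0 * x
        observed = np.ones(100, bool)
        observed[60:] = False
        out = proper_normal_linear_draw(X, y.copy(), observed, rng)
        np.testing.assert_allclose(out[60:], 2.0 + 3.0 * x[60:], atol=1e-8)

    def test_too_few_complete_cases(self):
        X = np.ones((5, 4))
        with pytest.raises(TooFewCasesError):
            proper_normal_linear_draw(
                X, np.zeros(5), np.array([True, True, False, False, False]),
                np.random.default_rng(0),
            )

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), x, x])
        obs = np.ones(30, bool)
        obs[-5:] = False
        with pytest.raises(SingularDesignError, match="dup"):
            proper_normal_linear_draw(
                X, rng.standard_normal(30), obs, rng, names=["intercept", "dup_a", "dup_b"]
            )

    def test_mcar_deleted_slope_recovered_by_repeated_imputation(self):
        """Parameter-recovery oracle: imputing a 50% MCAR-deleted outcome from
        its proxy recovers the full-data regression slope."""
        cohort = generate_cohort(CohortParams(n=20_000, rho=0.7), 5)
        rng = np.random.default_rng(6)
        observed = rng.random(len(cohort)) < 0.5
        X = np.column_stack([np.ones(len(cohort)), cohort.ks4])
        slopes = []
        for _ in range(40):
            completed = proper_normal_linear_draw(X, cohort.iq.copy(), observed, rng)
            slopes.append(ols(X, completed).beta[1])
        full = ols(X, cohort.iq).beta[1]
        assert np.mean(slopes) == pytest.approx(full, abs=0.01)


@pytest.fixture(scope="module")
def incomplete_cohort():
    cohort = generate_cohort(CohortParams(n=10_000, rho=0.7), 8)
    rng = np.random.default_rng(9)
    observed = rng.random(len(cohort)) < 0.5
    values = {"ks4": cohort.ks4, "iq": cohort.iq}
    return values, {"iq": observed}


class TestChained:
    def test_monotone_pattern_matches_univariate_draw_distribution(self, incomplete_cohort):
        """With one incomplete variable the chain has no memory: imputed values
        after several cycles match single proper draws distributionally."""
        values, observed = incomplete_cohort
        specs = [ImputationModelSpec("iq", ("ks4",))]
        chained = chained_impute(values, observed, specs, m=3, cycles=4, seed=10)
        mask = ~observed["iq"]
        chained_vals = np.concatenate([c["iq"][mask] for c in chained.completed])

        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(len(values["iq"])), values["ks4"]])
        direct_vals = np.concatenate(
            [
                proper_normal_linear_draw(X, values["iq"].copy(), observed["iq"], rng)[mask]
                for _ in range(3)
            ]
        )
        assert len(chained_vals) >= 5000 and len(direct_vals) >= 5000
        stat, p = ks_2samp(chained_vals, direct_vals)
        assert p > 0.01

    def test_observed_cells_identical_across_copies(self, incomplete_cohort):
        values, observed = incomplete_cohort
        specs = [ImputationModelSpec("iq", ("ks4",))]
        out = chained_impute(values, observed, specs, m=4, cycles=2, seed=12)
        assert out.m == 4
        for c in out.completed:
            np.testing.assert_array_equal(
                c["iq"][observed["iq"]], values["iq"][observed["iq"]]
            )

    def test_two_incomplete_variables_both_completed(self):
        cohort = generate_cohort(CohortParams(n=5_000, rho=0.7), 13)
        rng = np.random.default_rng(14)
        obs_iq = rng.random(len(cohort)) < 0.6
        obs_ks4 = rng.random(len(cohort)) < 0.8
        values = {"iq": cohort.iq, "ks4": cohort.ks4, "sex": cohort.sex.astype(float)}
        observed = {"iq": obs_iq, "ks4": obs_ks4}
        specs = [
            ImputationModelSpec("iq", ("sex", "ks4")),
            ImputationModelSpec("ks4", ("sex", "iq")),
        ]
        out = chained_impute(values, observed, specs, m=2, cycles=5, seed=15)
        for c in out.completed:
            assert np.isfinite(c["iq"]).all() and np.isfinite(c["ks4"]).all()
            np.testing.assert_array_equal(c["ks4"][obs_ks4], cohort.ks4[obs_ks4])

    def test_target_cannot_predict_itself(self):
        with pytest.raises(ValueError):
            ImputationModelSpec("iq", ("iq", "ks4"))

    def test_m_below_two_rejected(self, incomplete_cohort):
        values, observed = incomplete_cohort
        with pytest.raises(ValueError):
            chained_impute(
                values, observed, [ImputationModelSpec("iq", ("ks4",))], m=1, cycles=1, seed=0
            )


class TestRubinPooling:
    def test_hand_computed_two_imputation_example(self):
        pooled = pool_rubin([[0.1], [0.3]], [[0.01], [0.01]])
        assert pooled.qbar[0] == pytest.approx(0.2)
        assert pooled.within[0] == pytest.approx(0.01)
        assert pooled.between[0] == pytest.approx(0.02)
        assert pooled.total[0] == pytest.approx(0.04)

    def test_identical_estimates_give_zero_fmi(self):
        pooled = pool_rubin([[0.5], [0.5], [0.5]], [[0.02], [0.02], [0.02]])
        assert pooled.between[0] == 0.0
        assert pooled.total[0] == pooled.within[0]
        assert pooled.fmi[0] == 0.0

    def test_fmi_increases_with_between_variance(self):
        base = pool_rubin([[0.1], [0.2], [0.3]], [[0.01]] * 3)
        spread = pool_rubin([[0.0], [0.2], [0.4]], [[0.01]] * 3)
        assert spread.fmi[0] > base.fmi[0]

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([[0.1]], [[0.01]])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        est=st.lists(st.floats(-10, 10), min_size=3, max_size=12),
        w=st.floats(1e-6, 5.0),
    )
    def test_pooling_identities_hold(self, est, w):
        m = len(est)
        pooled = pool_rubin(np.array(est)[:, None], np.full((m, 1), w))
        b = np.var(est, ddof=1)
        assert pooled.total[0] == pytest.approx(w + (1 + 1 / m) * b, rel=1e-12)
        r = pooled.r[0]
        if 0 < r < np.inf:
            nu = (m - 1) * (1 + 1 / r) ** 2
            assert pooled.df[0] == pytest.approx(nu, rel=1e-12)
            assert pooled.fmi[0] == pytest.approx((r + 2 / (nu + 3)) / (r + 1), rel=1e-12)
        assert 0.0 <= pooled.fmi[0] <= 1.0
        assert pooled.between[0] >= 0.0
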