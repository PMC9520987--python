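"""Classical MR estimators: first stage, 2SLS, Wald ratio, mediation, two-sample."""

import numpy as np
import pytest

import mrnet
from mrnet.classical import validate_summary_stats
from mrnet.errors import (
    CollinearityError,
    DataError,
    VariantLookupError,
    WeakInstrumentError,
)

import pandas as pd


def _confounded_iv_data(n, seed, alpha=0.5, beta=0.4, conf=1.0):
    rng = np.random.default_rng(seed)
    iv = rng.binomial(2, 0.3, n).astype(float)
    u = rng.standard_normal(n)
    x = alpha * iv + conf * u + rng.standard_normal(n)
    y = beta * x + conf * u + rng.standard_normal(n)
    return iv, x, y, u


class TestFirstStage:
    def test_noiseless_single_iv(self):
        iv = np.arange(10, dtype=float)
        fit = mrnet.first_stage_predict(2 * iv, iv)
        assert fit.alpha[0] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert np.isinf(fit.f_statistic)

    def test_recovers_joint_alphas(self):
        rng = np.random.default_rng(0)
        n = 20_000
        Z = rng.binomial(2, 0.3, (n, 2)).astype(float)
        x = Z @ [0.4, 0.3] + rng.standard_normal(n)
        fit = mrnet.first_stage_predict(x, Z)
        np.testing.assert_allclose(fit.alpha, [0.4, 0.3], atol=0.03)

    def test_orthogonal_instruments_match_marginal_slopes(self):
        # joint least squares on independent instruments ~ per-IV marginal slopes
        rng = np.random.default_rng(1)
        n = 20_000
        Z = rng.standard_normal((n, 3))
        x = Z @ [0.5, -0.2, 0.3] + rng.standard_normal(n)
        fit = mrnet.first_stage_predict(x, Z)
        Zc = Z - Z.mean(axis=0)
        xc = x - x.mean()
        marginal = (Zc.T @ xc) / (Zc**2).sum(axis=0)
        np.testing.assert_allclose(fit.alpha, marginal, atol=0.03)

    def test_collinear_instruments_named(self):
        z = np.random.default_rng(2).standard_normal(100)
        with pytest.raises(CollinearityError) as err:
            mrnet.first_stage_predict(z, np.column_stack([z, z]), instrument_ids=["a", "b"])
        assert "b" in str(err.value)


class TestMultivariableMR:
    def test_null_response_gives_null_betas(self):
        rng = np.random.default_rng(3)
        n = 5000
        Z1 = rng.binomial(2, 0.3, n).astype(float)
        Z2 = rng.binomial(2, 0.3, n).astype(float)
        x1 = 0.5 * Z1 + rng.standard_normal(n)
        x2 = 0.5 * Z2 + rng.standard_normal(n)
        y = rng.standard_normal(n)
        fits = [
            mrnet.first_stage_predict(x1, Z1, entity="x1"),
            mrnet.first_stage_predict(x2, Z2, entity="x2"),
        ]
        for est in mrnet.multivariable_mr(y, fits):
            assert abs(est.beta) < 3 * est.se

    def test_recovers_joint_effects_under_confounding(self):
        # two instrumented exposures with a shared confounder of everything
        rng = np.random.default_rng(4)
        n = 20_000
        Z1 = rng.binomial(2, 0.3, n).astype(float)
        Z2 = rng.binomial(2, 0.3, n).astype(float)
        u = rng.standard_normal(n)
        x1 = 0.5 * Z1 + u + rng.standard_normal(n)
        x2 = 0.5 * Z2 + u + rng.standard_normal(n)
        y = 0.5 * x1 - 0.3 * x2 + u + rng.standard_normal(n)
        fits = [
            mrnet.first_stage_predict(x1, Z1, entity="x1"),
            mrnet.first_stage_predict(x2, Z2, entity="x2"),
        ]
        est = {e.exposure: e.beta for e in mrnet.multivariable_mr(y, fits)}
        assert est["x1"] == pytest.approx(0.5, abs=0.05)
        assert est["x2"] == pytest.approx(-0.3, abs=0.05)

    def test_single_exposure_equals_wald_ratio(self):
        for seed in range(20):
            iv, x, y, _ = _confounded_iv_data(400, seed)
            fit = mrnet.first_stage_predict(x, iv)
            tsls = mrnet.multivariable_mr(y, [fit])[0].beta
            ivc = iv - iv.mean()
            wald = (ivc @ (y - y.mean())) / (ivc @ (x - x.mean()))
            assert tsls == pytest.approx(wald, abs=1e-8)

    def test_matches_independent_iv2sls_implementation(self):
        # cross-check point estimate and se against statsmodels' IV2SLS
        from statsmodels.sandbox.regression.gmm import IV2SLS

        rng = np.random.default_rng(11)
        n = 3000
        Z = rng.binomial(2, 0.3, (n, 2)).astype(float)
        u = rng.standard_normal(n)
        x = Z @ [0.5, 0.4] + u + rng.standard_normal(n)
        y = 0.4 * x + u + rng.standard_normal(n)
        fit = mrnet.first_stage_predict(x, Z, entity="x")
        mine = mrnet.multivariable_mr(y, [fit])[0]
        sm = IV2SLS(
            y, np.column_stack([np.ones(n), x]), np.column_stack([np.ones(n), Z])
        ).fit()
        assert mine.beta == pytest.approx(sm.params[1], abs=1e-8)
        assert mine.se == pytest.approx(sm.bse[1], rel=0.02)

    def test_bootstrap_se_close_to_sandwich(self):
        iv, x, y, _ = _confounded_iv_data(4000, 7)
        fit = mrnet.first_stage_predict(x, iv)
        sandwich = mrnet.multivariable_mr(y, [fit])[0].se
        boot = mrnet.multivariable_mr(y, [fit], se_method="bootstrap", n_boot=400, seed=1)[0].se
        assert boot == pytest.approx(sandwich, rel=0.25)


class TestWaldRatio:
    def test_printed_rule_arithmetic(self):
        assert mrnet.wald_ratio(0.2, 0.01, 0.4, 0.01).beta == pytest.approx(0.5)
        assert mrnet.wald_ratio(0.0, 0.01, 0.4, 0.01).beta == 0.0

    def test_weak_denominator_rejected(self):
        with pytest.raises(WeakInstrumentError):
            mrnet.wald_ratio(0.2, 0.01, 0.0, 0.01)
        with pytest.raises(WeakInstrumentError):
            mrnet.wald_ratio(0.2, 0.01, 0.01, 0.05)  # |t| = 0.2 < 2

    def test_delta_method_se_matches_parametric_bootstrap(self):
        est = mrnet.wald_ratio(0.2, 0.02, 0.4, 0.02)
        rng = np.random.default_rng(0)
        draws = rng.normal(0.2, 0.02, 100_000) / rng.normal(0.4, 0.02, 100_000)
        assert est.se == pytest.approx(draws.std(), rel=0.05)


class TestMediation:
    def _mediation_data(self, n, seed):
        rng = np.random.default_rng(seed)
        iv1 = rng.binomial(2, 0.3, n).astype(float)
        iv2 = rng.binomial(2, 0.3, n).astype(float)
        u = rng.standard_normal(n)
        x = 0.6 * iv1 + u + rng.standard_normal(n)
        m = 0.5 * x + 0.6 * iv2 + u + rng.standard_normal(n)
        y = 0.3 * x + 0.4 * m + u + rng.standard_normal(n)
        return x, m, y, iv1, iv2

    def test_identity_holds_to_machine_precision(self):
        x, m, y, iv1, iv2 = self._mediation_data(2000, 0)
        est = mrnet.two_step_mediation(x, m, y, iv1, iv2)
        assert est.phi == est.beta_total - est.tau * est.gamma

    def test_disconnected_mediator_gives_phi_equal_total(self):
        rng = np.random.default_rng(5)
        n = 20_000
        iv1 = rng.binomial(2, 0.3, n).astype(float)
        iv2 = rng.binomial(2, 0.3, n).astype(float)
        x = 0.6 * iv1 + rng.standard_normal(n)
        m = 0.6 * iv2 + rng.standard_normal(n)  # gamma = 0 by construction
        y = 0.5 * x + rng.standard_normal(n)
        est = mrnet.two_step_mediation(x, m, y, iv1, iv2)
        assert est.phi == pytest.approx(est.beta_total, abs=0.05)

    def test_direct_effect_consistency(self):
        x, m, y, iv1, iv2 = self._mediation_data(50_000, 6)
        est = mrnet.two_step_mediation(x, m, y, iv1, iv2)
        assert est.phi == pytest.approx(0.3, abs=0.05)
        assert est.tau == pytest.approx(0.5, abs=0.05)
        assert est.gamma == pytest.approx(0.4, abs=0.05)

    def test_weak_first_stage_raises(self):
        rng = np.random.default_rng(7)
        n = 500
        iv1 = rng.binomial(2, 0.3, n).astype(float)
        iv2 = rng.binomial(2, 0.3, n).astype(float)
        x = rng.standard_normal(n)  # iv1 irrelevant
        m = 0.5 * x + 0.6 * iv2 + rng.standard_normal(n)
        y = 0.4 * m + rng.standard_normal(n)
        with pytest.raises(WeakInstrumentError):
            mrnet.two_step_mediation(x, m, y, iv1, iv2)


class TestTwoSamplePredict:
    def _setup(self):
        geno = mrnet.simulate_genotypes(200, 3, seed=1, maf=[0.2, 0.3, 0.4])
        table = pd.DataFrame(
            {"variant_id": geno.variant_ids, "beta": [0.0, 0.0, 0.0], "se": [0.1] * 3}
        )
        return geno, table

    def test_zero_betas_give_zero_prediction(self):
        geno, table = self._setup()
        assert (mrnet.two_sample_predict(table, geno) == 0).all()

    def test_unit_beta_recovers_dosage_column(self):
        geno, table = self._setup()
        table.loc[1, "beta"] = 1.0
        one = mrnet.two_sample_predict(table[table.index == 1], geno)
        np.testing.assert_array_equal(one, geno.column(geno.variant_ids[1]))

    def test_missing_variant_listed(self):
        geno, table = self._setup()
        table.loc[0, "variant_id"] = "absent"
        with pytest.raises(VariantLookupError) as err:
            mrnet.two_sample_predict(table, geno)
        assert "absent" in str(err.value)

    def test_correlated_variants_warn(self):
        geno = mrnet.simulate_genotypes(300, 1, seed=2, maf=[0.4])
        dup = mrnet.GenotypeMatrix(
            geno.sample_ids,
            ["a", "b"],
            np.column_stack([geno.dosages, geno.dosages]),
            np.array([0.4, 0.4]),
        )
        table = pd.DataFrame({"variant_id": ["a", "b"], "beta": [0.5, 0.5], "se": [0.1, 0.1]})
        with pytest.warns(UserWarning, match="uncorrelated"):
            mrnet.two_sample_predict(table, dup)

    def test_duplicate_summary_ids_rejected(self):
        table = pd.DataFrame({"variant_id": ["a", "a"], "beta": [0.1, 0.2], "se": [0.1, 0.1]})
        with pytest.raises(DataError):
            validate_summary_stats(table)


class TestInstrumentStrength:
    def test_noiseless_passes(self):
        iv = np.arange(50, dtype=float)
        fit = mrnet.first_stage_predict(3 * iv, iv)
        passed, report = mrnet.instrument_strength(fit, threshold=10)
        assert passed and np.isinf(report["f_statistic"])

    def test_irrelevant_instrument_fails(self):
        rng = np.random.default_rng(8)
        fit = mrnet.first_stage_predict(rng.standard_normal(1000), rng.standard_normal(1000))
        passed, _ = mrnet.instrument_strength(fit, threshold=10)
        assert not passed

    def test_zero_threshold_always_passes(self):
        rng = np.random.default_rng(9)
        fit = mrnet.first_stage_predict(rng.standard_normal(100), rng.standard_normal(100))
        assert mrnet.instrument_strength(fit, threshold=0)[0]


def test_confounded_ols_is_biased_while_mr_is_not():
    """With a confounder U of X and Y, OLS drifts by cov(U,X)*conf/var(X); 2SLS does not."""
    n = 100_000
    iv, x, y, _ = _confounded_iv_data(n, 10, alpha=0.5, beta=0.4, conf=1.0)
    # analytic: var(x) = 0.25*var(iv) + 1 + 1; bias = conf^2 / var(x)
    var_iv = 2 * 0.3 * 0.7
    var_x = 0.25 * var_iv + 2.0
    expected_ols = 0.4 + 1.0 / var_x
    ols = np.polyfit(x, y, 1)[0]
    assert ols == pytest.approx(expected_ols, abs=0.03)
    fit = mrnet.first_stage_predict(x, iv)
    mr = mrnet.multivariable_mr(y, [fit])[0].beta
    assert mr == pytest.approx(0.4, abs=0.05)
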