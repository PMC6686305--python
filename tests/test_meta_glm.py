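import numpy as np
import pandas as pd
import pytest

from tempocc.meta_glm import (
    ChainConfig,
    DESK_CHAIN,
    PAPER_CHAIN,
    GlmFit,
    GlmSpec,
    chain_diagnostics,
    delta_dic,
    fit_binomial,
    fit_glmm,
    fit_multinomial,
    hpd_interval,
    predict_proba_binomial,
    predict_proba_multinomial,
)
from tempocc.synthetic import generate_outcome_table
from tempocc.outcomes import records_to_frame

QUICK = ChainConfig(iterations=26_000, burn_in=1_000, thinning=25)


def frame(outcomes, x):
    return pd.DataFrame(
        {
            "outcome": outcomes,
            "x": x,
            "dataset_id": [f"d{i}" for i in range(len(outcomes))],
        }
    )


def binom_frame(y, x):
    return frame(["aggregation" if yi else "random" for yi in y], x)


class TestChainConfig:
    def test_paper_preset_retains_1998_samples(self):
        assert PAPER_CHAIN.retained == (10_000_000 - 10_000) // 5_000 == 1998

    def test_desk_preset_retains_2000(self):
        assert DESK_CHAIN.retained == 2000

    def test_too_few_retained_rejected(self):
        with pytest.raises(ValueError, match="1,000"):
            ChainConfig(iterations=2000, burn_in=1000, thinning=10)


class TestHpd:
    def test_matches_arviz_on_skewed_sample(self):
        arviz = pytest.importorskip("arviz")
        x = np.random.default_rng(0).gamma(2.0, 1.0, 4000)
        lo, hi = hpd_interval(x, 0.95)
        ref = arviz.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)


class TestFitBinomial:
    def test_intercept_only_matches_log_odds(self):
        # 7 successes of 10 under a near-flat prior: posterior mean of the
        # intercept should sit near log(7/3)
        df = binom_frame([1] * 7 + [0] * 3, np.zeros(10))
        spec = GlmSpec(predictor=None, prior_scale=1000.0, chain=QUICK)
        fit = fit_binomial(df, spec, np.random.default_rng(1))
        assert fit.posterior_mean[0] == pytest.approx(np.log(7 / 3), abs=0.15)

    def test_complete_separation_stays_finite(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(int)  # perfectly separable
        spec = GlmSpec(predictor="x", prior_scale=25.0, chain=QUICK)
        fit = fit_binomial(binom_frame(y, x), spec, np.random.default_rng(2))
        assert np.isfinite(fit.posterior_mean).all()
        assert np.isfinite(fit.hpd).all()
        assert fit.significant

    def test_posterior_mean_matches_mle_when_well_separated(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        p = 1 / (1 + np.exp(-(0.3 + 0.9 * x)))
        y = (rng.random(400) < p).astype(int)
        spec = GlmSpec(predictor="x", prior_scale=1000.0, chain=QUICK)
        fit = fit_binomial(binom_frame(y, x), spec, rng)
        X = sm.add_constant((x - x.mean()) / x.std())
        mle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.posterior_mean[0] == pytest.approx(mle.params[0], abs=0.1)
        assert fit.posterior_mean[1] == pytest.approx(mle.params[1], abs=0.1)

    def test_fitted_probabilities_are_probabilities(self):
        df = binom_frame([1, 0, 1, 1, 0, 1, 0, 0], np.arange(8.0))
        spec = GlmSpec(predictor="x", chain=QUICK)
        fit = fit_binomial(df, spec, np.random.default_rng(4))
        p = predict_proba_binomial(fit, np.linspace(-2, 2, 9))
        assert np.all((p > 0) & (p < 1))

    def test_reproducible_given_seed(self):
        df = binom_frame([1, 0, 1, 1, 0, 1], np.arange(6.0))
        spec = GlmSpec(predictor="x", chain=QUICK)
        f1 = fit_binomial(df, spec, np.random.default_rng(9))
        f2 = fit_binomial(df, spec, np.random.default_rng(9))
        np.testing.assert_array_equal(f1.samples, f2.samples)


class TestFitMultinomial:
    def test_fitted_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        recs = generate_outcome_table(40, {"aggregation": 1.0}, rng)
        spec = GlmSpec(predictor="plot_size_ha", response="multinomial",
                       chain=QUICK)
        fit = fit_multinomial(records_to_frame(recs), spec, rng)
        probs = predict_proba_multinomial(fit, np.linspace(-2, 2, 7))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_intercept_only_recovers_category_frequencies(self):
        rng = np.random.default_rng(6)
        outcomes = (["aggregation"] * 30 + ["segregation"] * 50 + ["random"] * 20)
        df = frame(outcomes, np.zeros(100))
        spec = GlmSpec(predictor=None, response="multinomial", chain=QUICK)
        fit = fit_multinomial(df, spec, rng)
        probs = predict_proba_multinomial(fit, np.array([0.0]))[0]
        # categories: (random, aggregation, segregation)
        assert probs[0] == pytest.approx(0.20, abs=0.04)
        assert probs[1] == pytest.approx(0.30, abs=0.04)
        assert probs[2] == pytest.approx(0.50, abs=0.04)

    def test_detects_increasing_log_odds(self):
        rng = np.random.default_rng(7)
        recs = generate_outcome_table(50, {"aggregation": 1.5}, rng)  # n = 300
        spec = GlmSpec(predictor="plot_size_ha", response="multinomial",
                       chain=QUICK)
        fit = fit_multinomial(records_to_frame(recs), spec, rng)
        j = fit.param_names.index("beta_plot_size_ha_aggregation")
        lo, hi = fit.hpd[j]
        assert lo > 0
        assert fit.significant


class TestFitGlmm:
    def _grouped_frame(self, rng, sd, n_groups=19, n_per=24, beta=(0.2, 0.8)):
        u = rng.normal(0, sd, n_groups)
        rows = []
        for g in range(n_groups):
            x = rng.normal(size=n_per)
            eta = beta[0] + beta[1] * x + u[g]
            y = rng.random(n_per) < 1 / (1 + np.exp(-eta))
            for xi, yi in zip(x, y):
                rows.append(
                    {"outcome": "aggregation" if yi else "random", "x": xi,
                     "dataset_id": f"g{g:02d}"}
                )
        return pd.DataFrame(rows)

    def test_recovers_random_intercept_sd(self):
        rng = np.random.default_rng(8)
        df = self._grouped_frame(rng, sd=1.0)
        spec = GlmSpec(predictor="x", random_intercept=True,
                       chain=ChainConfig(41_000, 5_000, 36))
        fit = fit_glmm(df, spec, rng)
        sigma = np.exp(np.median(fit.samples[:, -1]))
        assert 0.5 <= sigma <= 1.6

    def test_zero_variance_truth_concentrates_near_zero(self):
        rng = np.random.default_rng(9)
        df = self._grouped_frame(rng, sd=0.0)
        spec = GlmSpec(predictor="x", random_intercept=True,
                       chain=ChainConfig(41_000, 5_000, 36))
        fit = fit_glmm(df, spec, rng)
        sigma = np.exp(np.median(fit.samples[:, -1]))
        assert sigma < 0.45

    def test_fixed_effects_agree_with_glm_when_groups_identical(self):
        rng = np.random.default_rng(10)
        df = self._grouped_frame(rng, sd=0.0, n_groups=6, n_per=60)
        spec = GlmSpec(predictor="x", random_intercept=True,
                       chain=ChainConfig(41_000, 5_000, 36))
        fit_mixed = fit_glmm(df, spec, rng)
        fit_fixed = fit_binomial(
            df, GlmSpec(predictor="x", chain=QUICK), np.random.default_rng(10)
        )
        assert fit_mixed.posterior_mean[1] == pytest.approx(
            fit_fixed.posterior_mean[1], abs=0.2
        )


class TestDic:
    def test_identical_model_gives_zero(self):
        df = binom_frame([1, 0, 1, 1, 0, 1], np.arange(6.0))
        fit = fit_binomial(df, GlmSpec(predictor="x", chain=QUICK),
                           np.random.default_rng(11))
        assert delta_dic(fit, fit) == 0.0

    def test_informative_predictor_beats_null(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-3.0 * x))).astype(int)
        df = binom_frame(y, x)
        fit = fit_binomial(df, GlmSpec(predictor="x", chain=QUICK), rng)
        null = fit_binomial(df, GlmSpec(predictor=None, chain=QUICK), rng)
        assert delta_dic(fit, null) > 20
        assert fit.p_d > 0 and null.p_d > 0


class TestDiagnostics:
    def _fit_with_samples(self, samples):
        samples = np.asarray(samples)
        return GlmFit(
            spec=GlmSpec(predictor=None, chain=QUICK),
            param_names=[f"p{i}" for i in range(samples.shape[1])],
            samples=samples,
            hpd=np.zeros((samples.shape[1], 2)),
            posterior_mean=samples.mean(axis=0),
            mean_deviance=0.0,
            p_d=0.0,
            dic=0.0,
            significant=False,
            acceptance_rate=0.3,
            lag1_autocorr=np.array(
                [np.corrcoef(samples[:-1, j], samples[1:, j])[0, 1]
                 for j in range(samples.shape[1])]
            ),
        )

    def test_white_noise_passes(self):
        x = np.random.default_rng(13).normal(size=(2000, 1))
        report = chain_diagnostics(self._fit_with_samples(x))
        assert report.ok

    def test_strong_ar1_flagged_with_advice(self):
        rng = np.random.default_rng(14)
        x = np.zeros(2000)
        for t in range(1, 2000):
            x[t] = 0.9 * x[t - 1] + rng.normal()
        report = chain_diagnostics(self._fit_with_samples(x[:, None]))
        assert not report.ok
        assert "lengthen" in report.advice
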