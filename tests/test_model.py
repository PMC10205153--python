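import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from erpseq.model import (
    ModelSpec,
    PosteriorSamples,
    PriorSpec,
    check_convergence,
    default_priors,
    drop_term,
    fit_model,
    prior_predictive,
    summarize_posterior,
)
from erpseq.simulate import TruthParams, simulate_trial_table


def dummy_samples(draws: dict) -> PosteriorSamples:
    any_v = next(iter(draws.values()))
    return PosteriorSamples(
        draws=draws,
        unconstrained=np.zeros(any_v.shape + (1,)),
        log_posterior=lambda x: np.zeros(len(np.atleast_2d(x))),
        layout=None,
        lmm=None,
        spec=None,
        seed=0,
    )


class TestPriorSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            PriorSpec("normal", scale=-1.0)
        with pytest.raises(ValueError):
            PriorSpec("lkj", lkj_eta=0.0)
        with pytest.raises(ValueError):
            PriorSpec("weird")

    def test_truncated_density_integrates_to_one(self):
        # the one-sided N-(0, 0.2) prior must be correctly renormalized
        p = PriorSpec("truncated_normal", 0.0, 0.2, "negative_only")
        val, _ = integrate.quad(lambda x: np.exp(p.logpdf(np.array([x]))[0]), -np.inf, 0)
        assert abs(val - 1.0) < 1e-8
        # and assigns zero mass to the positive side
        assert p.logpdf(np.array([0.1]))[0] == -np.inf

    def test_positive_truncation_with_shifted_loc(self):
        p = PriorSpec("truncated_normal", 8.0, 2.0, "positive_only")
        val, _ = integrate.quad(lambda x: np.exp(p.logpdf(np.array([x]))[0]), 0, np.inf)
        assert abs(val - 1.0) < 1e-8

    def test_rvs_respects_support(self, rng):
        p = PriorSpec("truncated_normal", 0.0, 0.2, "negative_only")
        x = p.rvs(rng, size=500)
        assert (x < 0).all()


class TestModelSpecValidation:
    def test_missing_prior_errors(self):
        with pytest.raises(ValueError, match="prior"):
            ModelSpec("amplitude", ["x"], priors={"intercept": PriorSpec()})

    def test_default_priors_complete(self):
        spec = ModelSpec(
            "amplitude", ["x"], random_subject=["intercept", "x"], random_item=True
        )
        assert set(spec.priors) >= {"intercept", "x", "sigma_subject", "sigma_item",
                                    "sigma_residual", "rho"}

    def test_drop_term_keeps_random_effects(self):
        spec = ModelSpec("amplitude", ["x"], random_subject=["intercept", "x"])
        null = drop_term(spec, "x")
        assert null.fixed_terms == []
        assert null.random_subject == ["intercept", "x"]
        with pytest.raises(ValueError):
            drop_term(spec, "missing")


class TestFitConjugate:
    def test_posterior_matches_analytic(self, conjugate_data):
        table, spec, sigma = conjugate_data
        fit = fit_model(table, spec, chains=4, iterations=6000, warmup=1000, seed=2)
        X = np.column_stack([np.ones(len(table)), table["x"]])
        y = table["amplitude"].to_numpy()
        S0 = np.diag([25.0, 1.0])
        Sn = np.linalg.inv(np.linalg.inv(S0) + X.T @ X / sigma**2)
        mn = Sn @ (X.T @ y / sigma**2)
        sd = np.sqrt(np.diag(Sn))
        summ = summarize_posterior(fit)
        for j, name in enumerate(["b_intercept", "b_x"]):
            assert summ.loc[name, "mean"] == pytest.approx(mn[j], abs=0.02 * 3 * sd[j])
            draw_sd = fit.stacked(name).std()
            assert draw_sd == pytest.approx(sd[j], rel=0.05)

    def test_zero_re_data_recovers_beta(self, rng):
        # data with no random effects, fitted with none and known sigma
        truth = TruthParams(
            beta_constraint=-0.26,
            sigma_subject=np.zeros(3),
            sigma_item=0.0,
            sigma_residual=2.0,
        )
        _, _, table = simulate_trial_table(truth, 6, 16, seed=8)
        spec = ModelSpec(
            "amplitude",
            ["entropy_centered"],
            random_subject=[],
            random_item=False,
            priors={"intercept": PriorSpec("normal", 0, 5), "entropy_centered": PriorSpec("normal", 0, 1)},
            sigma_residual_fixed=2.0,
        )
        fit = fit_model(table, spec, iterations=3000, warmup=800, seed=3)
        summ = summarize_posterior(fit)
        sd = fit.stacked("b_entropy_centered").std()
        assert abs(summ.loc["b_entropy_centered", "mean"] - (-0.26)) < 3 * sd


class TestCheckConvergence:
    def test_white_noise_chains_pass(self, rng):
        draws = {"a": rng.standard_normal((4, 3000))}
        rep = check_convergence(dummy_samples(draws), rhat_max=1.01, ess_min=2000)
        assert rep.passed

    def test_offset_chain_fails_rhat(self, rng):
        d = rng.standard_normal((2, 2000))
        d[1] += 5.0
        rep = check_convergence(dummy_samples({"a": d}), rhat_max=1.01, ess_min=10)
        assert not rep.passed
        assert rep.table.loc[0, "rhat"] > 1.01

    def test_too_few_draws_fail_ess(self, rng):
        rep = check_convergence(
            dummy_samples({"a": rng.standard_normal((2, 5))}), ess_min=2000
        )
        assert not rep.passed


class TestSummarize:
    def test_quantile_interpolation(self):
        draws = {"a": np.arange(1.0, 101.0).reshape(2, 50)}
        summ = summarize_posterior(dummy_samples(draws))
        assert summ.loc["a", "mean"] == pytest.approx(50.5)
        assert summ.loc["a", "lower"] == pytest.approx(3.475)
        assert summ.loc["a", "upper"] == pytest.approx(97.525)

    def test_constant_draws(self):
        summ = summarize_posterior(dummy_samples({"a": np.full((2, 100), 2.5)}))
        assert summ.loc["a", "lower"] == summ.loc["a", "upper"] == 2.5

    def test_symmetric_draws(self, rng):
        d = rng.standard_normal((2, 5000))
        d = np.concatenate([d, -d], axis=1)
        summ = summarize_posterior(dummy_samples({"a": d}))
        assert abs(summ.loc["a", "mean"]) < 1e-12


class TestPriorPredictive:
    def _design(self):
        truth = TruthParams()
        _, _, table = simulate_trial_table(truth, 4, 8, seed=5)
        return table

    def test_degenerate_scales_collapse_to_intercept_spread(self):
        design = self._design()
        priors = default_priors(["entropy_centered"])
        priors.update(
            {
                "entropy_centered": PriorSpec("normal", 0, 1e-8),
                "sigma_subject": PriorSpec("truncated_normal", 0, 1e-8, "positive_only"),
                "sigma_item": PriorSpec("truncated_normal", 0, 1e-8, "positive_only"),
                "sigma_residual": PriorSpec("truncated_normal", 1e-8, 1e-8, "positive_only"),
            }
        )
        spec = ModelSpec(
            "amplitude", ["entropy_centered"],
            random_subject=["intercept", "entropy_centered"], random_item=True,
            priors=priors,
        )
        out = prior_predictive(spec, design, seed=1, n_draws=300)
        # each draw is flat at its intercept; across draws the sd matches N(0,5)
        assert np.allclose(out["amplitude"].std(axis=1), 0.0, atol=1e-6)
        assert out["amplitude"][:, 0].std() == pytest.approx(5.0, rel=0.2)

    def test_registered_priors_give_residual_scale_spread(self):
        design = self._design()
        spec = ModelSpec(
            "amplitude", ["entropy_centered"],
            random_subject=["intercept", "entropy_centered"], random_item=True,
        )
        out = prior_predictive(spec, design, seed=2, n_draws=300)
        within = out["amplitude"].std(axis=1).mean()
        assert 4.0 < within < 16.0  # of the order of the 8 uV residual prior

    def test_seed_reproducible(self):
        design = self._design()
        spec = ModelSpec("amplitude", ["entropy_centered"],
                         random_subject=["intercept"], random_item=True)
        a = prior_predictive(spec, design, seed=3, n_draws=50)
        b = prior_predictive(spec, design, seed=3, n_draws=50)
        np.testing.assert_array_equal(a["amplitude"], b["amplitude"])


class TestHierarchicalFitProperties:
    def _fit(self, table, seed=0, **kw):
        spec = ModelSpec(
            "amplitude", ["entropy_centered"],
            random_subject=["intercept", "entropy_centered"], random_item=True,
        )
        kw.setdefault("iterations", 1200)
        kw.setdefault("warmup", 800)
        return spec, fit_model(table, spec, seed=seed, **kw)

    def test_subject_label_exchangeability(self):
        truth = TruthParams(sigma_residual=3.0)
        _, _, table = simulate_trial_table(truth, 10, 16, seed=21)
        spec, fit1 = self._fit(table, seed=4)
        relabel = {s: f"z{i}" for i, s in enumerate(sorted(table["subject"].unique())[::-1])}
        table2 = table.assign(subject=table["subject"].map(relabel))
        _, fit2 = self._fit(table2, seed=4)
        m1 = fit1.stacked("b_entropy_centered")
        m2 = fit2.stacked("b_entropy_centered")
        mc = m1.std() * np.sqrt(1 / 200 + 1 / 200)  # generous MC allowance
        assert abs(m1.mean() - m2.mean()) < 4 * mc

    def test_likelihood_dominance_with_wider_priors(self):
        # well-identified data: 10x wider priors move the mean < 1 posterior SD
        truth = TruthParams(beta_constraint=-1.0, sigma_residual=1.0)
        _, _, table = simulate_trial_table(truth, 10, 16, seed=22)
        spec, fit1 = self._fit(table, seed=5)
        wide = {
            k: (
                PriorSpec(p.family, p.loc, p.scale * 10, p.truncation, p.lkj_eta)
                if p.family != "lkj"
                else p
            )
            for k, p in spec.priors.items()
        }
        spec_wide = ModelSpec(
            "amplitude", ["entropy_centered"],
            random_subject=["intercept", "entropy_centered"], random_item=True,
            priors=wide,
        )
        fit2 = fit_model(table, spec_wide, iterations=1200, warmup=800, seed=5)
        b1 = fit1.stacked("b_entropy_centered")
        b2 = fit2.stacked("b_entropy_centered")
        assert abs(b1.mean() - b2.mean()) < b1.std()

    def test_convergence_check_raises_with_report(self):
        from erpseq.model import ConvergenceError

        truth = TruthParams()
        _, _, table = simulate_trial_table(truth, 4, 8, seed=23)
        spec = ModelSpec(
            "amplitude", ["entropy_centered"],
            random_subject=["intercept", "entropy_centered"], random_item=True,
        )
        with pytest.raises(ConvergenceError) as exc:
            fit_model(
                table, spec, iterations=40, warmup=40, seed=6, check=(1.0001, 50000)
            )
        assert not exc.value.report.passed

    def test_empty_table_errors(self):
        spec = ModelSpec("amplitude", [], random_subject=[], random_item=False)
        with pytest.raises(ValueError):
            fit_model(pd.DataFrame({"amplitude": []}), spec)
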