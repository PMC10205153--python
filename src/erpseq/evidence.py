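"""Marginal likelihoods and Bayes factors.

The log marginal likelihood is estimated by iterative bridge sampling
(Meng & Wong optimal bridge) on the unconstrained parameterization of the
collapsed posterior. The proposal is a moment-matched multivariate normal
fitted to half the posterior draws; the other half enters the bridge
identity, so the proposal fit and the estimator use disjoint draws.

Because the random effects are marginalized analytically inside the model
density, bridge sampling operates on a low-dimensional space and the
priors (including one-sided truncation factors) are fully normalized, so
log marginal likelihoods are directly comparable across prior sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .model import ModelSpec, PosteriorSamples, PriorSpec, drop_term, fit_model, with_prior

__all__ = [
    "EvidenceResult",
    "SensitivityCurve",
    "log_marginal_likelihood",
    "bayes_factor",
    "classify_bf",
    "bayes_factor_for_term",
    "sensitivity_sweep",
    "savage_dickey_check",
]


@dataclass(frozen=True)
class EvidenceResult:
    log_ml: float
    log_ml_mc_error: float
    n_posterior_draws: int
    n_proposal_draws: int
    prior_set_id: str
    data_fingerprint: str
    n_iterations: int = 0
    converged: bool = True


def log_marginal_likelihood(
    samples: PosteriorSamples,
    seed: int = 0,
    *,
    n_proposal_draws: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    max_draws: int = 4000,
) -> EvidenceResult:
    """Bridge-sampling estimate of the log marginal likelihood.

    Uses the unnormalized log posterior attached to ``samples`` (normalized
    priors x collapsed likelihood, with transformation Jacobians). Draws
    are thinned evenly to at most ``max_draws`` before splitting; the
    estimate is invariant to the thinning rate up to Monte-Carlo error.
    """
    xs = samples.unconstrained.reshape(-1, samples.unconstrained.shape[-1])
    if xs.shape[0] > max_draws:
        stride = int(np.ceil(xs.shape[0] / max_draws))
        xs = xs[::stride]
    d = xs.shape[1]
    # even/odd split balances chains between proposal fit and evaluation
    fit_half = xs[0::2]
    eval_half = xs[1::2]
    n1 = eval_half.shape[0]
    n2 = n_proposal_draws or n1

    mean = fit_half.mean(axis=0)
    cov = np.cov(fit_half.T).reshape(d, d) + 1e-10 * np.eye(d)
    rng = np.random.default_rng(seed)
    prop = rng.multivariate_normal(mean, cov, size=n2, method="cholesky")

    mvn = stats.multivariate_normal(mean=mean, cov=cov, allow_singular=True)
    lp_eval = samples.log_posterior(eval_half)
    if not np.all(np.isfinite(lp_eval)):
        bad = int(np.argmax(~np.isfinite(lp_eval)))
        raise ValueError(
            f"non-finite posterior density at posterior draw {bad}; "
            f"parameters: {samples.layout.names}"
        )
    l1 = lp_eval - mvn.logpdf(eval_half)
    l2 = samples.log_posterior(prop) - mvn.logpdf(prop)

    lstar = np.median(l1)
    l1 = l1 - lstar
    l2 = l2 - lstar
    log_s1 = np.log(n1 / (n1 + n2))
    log_s2 = np.log(n2 / (n1 + n2))

    log_r = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        num = logsumexp(l2 - np.logaddexp(log_s1 + l2, log_s2 + log_r)) - np.log(n2)
        den = logsumexp(-np.logaddexp(log_s1 + l1, log_s2 + log_r)) - np.log(n1)
        log_r_new = num - den
        if abs(log_r_new - log_r) <= tol * max(abs(log_r), 1.0):
            log_r = log_r_new
            converged = True
            break
        log_r = log_r_new

    # iid approximation to the relative mean-squared error of the estimate
    lf2 = l2 - np.logaddexp(log_s1 + l2, log_s2 + log_r)
    lf1 = -np.logaddexp(log_s1 + l1, log_s2 + log_r)
    re2 = _rel_var(lf2) / n2 + _rel_var(lf1) / n1
    mc_error = float(np.sqrt(max(re2, 0.0)))

    return EvidenceResult(
        log_ml=float(log_r + lstar),
        log_ml_mc_error=mc_error,
        n_posterior_draws=n1,
        n_proposal_draws=n2,
        prior_set_id=samples.spec.prior_set_id,
        data_fingerprint=samples.lmm.fingerprint,
        n_iterations=it,
        converged=converged,
    )


def _rel_var(logf: np.ndarray) -> float:
    # Var(f)/E(f)^2 computed stably as E[(f/E f - 1)^2]
    m = logsumexp(logf) - np.log(logf.size)
    ratio = np.exp(logf - m)
    return float(np.mean((ratio - 1.0) ** 2))


def classify_bf(bf10: float) -> str:
    if bf10 >= 10:
        return "strong H1"
    if bf10 >= 3:
        return "supports H1"
    if bf10 <= 1 / 10:
        return "strong H0"
    if bf10 <= 1 / 3:
        return "supports H0"
    return "inconclusive"


def bayes_factor(full: EvidenceResult, null: EvidenceResult) -> tuple[float, str]:
    """BF10 = exp(log ML_full - log ML_null), with an evidence label."""
    if full.data_fingerprint != null.data_fingerprint:
        raise ValueError("evidence results computed on different data")
    bf10 = float(np.exp(full.log_ml - null.log_ml))
    return bf10, classify_bf(bf10)


def bayes_factor_for_term(
    table: pd.DataFrame,
    spec: ModelSpec,
    term: str,
    seed: int = 0,
    *,
    fit_kwargs: dict | None = None,
    null_samples: PosteriorSamples | None = None,
) -> dict:
    """Fit full and nested null models for ``term`` and bridge both.

    The null model drops only the fixed effect; random effects and all
    other terms are retained.
    """
    fit_kwargs = dict(fit_kwargs or {})
    full_fit = fit_model(table, spec, seed=seed, **fit_kwargs)
    if null_samples is None:
        null_fit = fit_model(table, drop_term(spec, term), seed=seed + 1, **fit_kwargs)
    else:
        null_fit = null_samples
    ev_full = log_marginal_likelihood(full_fit, seed=seed + 2)
    ev_null = log_marginal_likelihood(null_fit, seed=seed + 3)
    bf10, label = bayes_factor(ev_full, ev_null)
    return {
        "bf10": bf10,
        "label": label,
        "full": ev_full,
        "null": ev_null,
        "full_fit": full_fit,
        "null_fit": null_fit,
    }


@dataclass
class SensitivityCurve:
    term: str
    table: pd.DataFrame  # columns: prior_scale, truncation, bf10, label

    def bf(self, scale: float, truncation: str) -> float:
        t = self.table
        row = t[(t.prior_scale == scale) & (t.truncation == truncation)]
        return float(row.bf10.iloc[0])


def sensitivity_sweep(
    table: pd.DataFrame,
    spec: ModelSpec,
    term: str,
    scales=(0.2, 0.5, 1.0, 2.0),
    variants=("truncated", "untruncated"),
    truncation_side: str = "negative_only",
    seed: int = 0,
    *,
    fit_kwargs: dict | None = None,
) -> SensitivityCurve:
    """BF10 for a grid of prior scales on ``term``, all other priors fixed.

    The null model does not depend on the tested term's prior, so it is
    fitted and bridged once and shared across the grid.
    """
    fit_kwargs = dict(fit_kwargs or {})
    null_fit = fit_model(table, drop_term(spec, term), seed=seed + 1, **fit_kwargs)
    rows = []
    k = 0
    for variant in variants:
        for scale in scales:
            if variant == "truncated":
                prior = PriorSpec("truncated_normal", 0.0, scale, truncation_side)
            else:
                prior = PriorSpec("normal", 0.0, scale)
            spec_k = with_prior(spec, term, prior)
            out = bayes_factor_for_term(
                table, spec_k, term, seed=seed + 10 * (k + 1),
                fit_kwargs=fit_kwargs, null_samples=null_fit,
            )
            rows.append(
                {
                    "prior_scale": scale,
                    "truncation": variant,
                    "bf10": out["bf10"],
                    "label": out["label"],
                }
            )
            k += 1
    return SensitivityCurve(term=term, table=pd.DataFrame(rows))


def savage_dickey_check(
    samples: PosteriorSamples, prior: PriorSpec, term: str, *, bw_method=None
) -> float:
    """Savage-Dickey BF10 for a point null at 0: prior(0) / posterior(0).

    Valid only for an untruncated continuous prior on the tested term.
    The posterior density at 0 is a Gaussian kernel density estimate.
    """
    if prior.effective_truncation != "none":
        raise ValueError("Savage-Dickey requires an untruncated prior")
    draws = samples.stacked(f"b_{term}")
    kde = stats.gaussian_kde(draws, bw_method=bw_method)
    post0 = float(kde(0.0)[0])
    near0 = np.mean(np.abs(draws) < 2 * draws.std())
    if post0 <= 0 or near0 < 0.01:
        warnings.warn("sparse posterior mass near 0; widening KDE bandwidth")
        kde = stats.gaussian_kde(draws, bw_method=(kde.factor * 3))
        post0 = float(kde(0.0)[0])
    prior0 = float(np.exp(prior.logpdf(np.array([0.0]))[0]))
    return prior0 / post0
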