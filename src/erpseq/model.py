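"""Hierarchical Bayesian amplitude models.

Fits the single-trial amplitude model

    amplitude ~ intercept + fixed terms
                + (correlated by-subject intercept + slopes)
                + (by-item intercept) + residual

with truncated-normal / LKJ priors. The Gaussian random effects are
marginalized analytically (see :mod:`erpseq._lmm`), and the remaining
low-dimensional posterior (fixed effects + variance components) is
sampled with an adaptive random-walk Metropolis scheme initialized at the
posterior mode. Because the collapsed posterior density is normalized in
its priors, the same density function feeds the bridge-sampling marginal
likelihood estimator.

Estimation models use wide priors (betas ~ Normal(0, 1)); hypothesis-test
models use narrower, possibly one-sided Normal(0, 0.2)-family priors.
One-sided priors are half-normals with the truncation factor included, so
marginal likelihoods are comparable across prior sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._corr import (
    cholesky_from_partials,
    lkj_partials_logpdf,
    n_partials,
    sample_partials,
)
from ._lmm import CollapsedLMM

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "PosteriorSamples",
    "ConvergenceError",
    "ConvergenceReport",
    "default_priors",
    "fit_model",
    "check_convergence",
    "summarize_posterior",
    "prior_predictive",
    "drop_term",
    "with_prior",
]

INTERCEPT = "intercept"


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """A scalar prior (normal / one-sided truncated normal) or an LKJ prior."""

    family: str = "normal"  # normal | truncated_normal | lkj
    loc: float = 0.0
    scale: float = 1.0
    truncation: str = "none"  # none | negative_only | positive_only
    lkj_eta: float = 2.0

    def __post_init__(self):
        if self.family not in ("normal", "truncated_normal", "lkj"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("prior scale must be positive")
        if self.lkj_eta <= 0:
            raise ValueError("lkj_eta must be positive")
        if self.truncation not in ("none", "negative_only", "positive_only"):
            raise ValueError(f"unknown truncation {self.truncation!r}")
        # cache normalization constants (frozen dataclass -> setattr directly)
        a = (0.0 - self.loc) / self.scale
        if self.effective_truncation == "negative_only":
            logz = float(stats.norm.logcdf(a))
        elif self.effective_truncation == "positive_only":
            logz = float(stats.norm.logsf(a))
        else:
            logz = 0.0
        object.__setattr__(self, "_logz", logz)
        object.__setattr__(
            self, "_lognorm", -math.log(self.scale) - 0.5 * math.log(2.0 * math.pi) - logz
        )

    @property
    def effective_truncation(self) -> str:
        if self.family == "truncated_normal":
            return self.truncation
        return "none"

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = -0.5 * ((x - self.loc) / self.scale) ** 2 + self._lognorm
        trunc = self.effective_truncation
        if trunc == "negative_only":
            out = np.where(x < 0, out, -np.inf)
        elif trunc == "positive_only":
            out = np.where(x > 0, out, -np.inf)
        return out

    def rvs(self, rng: np.random.Generator, size=()) -> np.ndarray:
        trunc = self.effective_truncation
        if trunc == "none":
            return rng.normal(self.loc, self.scale, size=size)
        a, b = (-np.inf, 0.0) if trunc == "negative_only" else (0.0, np.inf)
        az, bz = (a - self.loc) / self.scale, (b - self.loc) / self.scale
        return stats.truncnorm.rvs(
            az, bz, loc=self.loc, scale=self.scale, size=size, random_state=rng
        )


def default_priors(fixed_terms: Sequence[str], *, random_item: bool = True) -> dict:
    """Estimation prior set: alpha~N(0,5), beta~N(0,1), sigma~half-normals,
    residual sigma ~ N+(8,2), correlations ~ LKJ(2)."""
    priors = {INTERCEPT: PriorSpec("normal", 0.0, 5.0)}
    for t in fixed_terms:
        priors[t] = PriorSpec("normal", 0.0, 1.0)
    priors["sigma_subject"] = PriorSpec("truncated_normal", 0.0, 0.5, "positive_only")
    if random_item:
        priors["sigma_item"] = PriorSpec("truncated_normal", 0.0, 0.5, "positive_only")
    priors["sigma_residual"] = PriorSpec("truncated_normal", 8.0, 2.0, "positive_only")
    priors["rho"] = PriorSpec("lkj", lkj_eta=2.0)
    return priors


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    response: str
    fixed_terms: list[str]
    random_subject: list[str] = field(default_factory=list)
    random_item: bool = True
    priors: dict[str, PriorSpec] = field(default_factory=dict)
    sigma_residual_fixed: float | None = None
    subject_col: str = "subject"
    item_col: str = "item"

    def __post_init__(self):
        if not self.priors:
            self.priors = default_priors(self.fixed_terms, random_item=self.random_item)
        for t in [INTERCEPT] + list(self.fixed_terms):
            if t not in self.priors:
                raise ValueError(f"no prior for fixed term {t!r}")
        # random slopes may reference columns that carry no fixed effect
        # (the nested null model drops the fixed term but keeps the slope)
        if self.random_subject and "sigma_subject" not in self.priors:
            raise ValueError("no prior for sigma_subject")
        if self.random_item and "sigma_item" not in self.priors:
            raise ValueError("no prior for sigma_item")
        if self.sigma_residual_fixed is None and "sigma_residual" not in self.priors:
            raise ValueError("no prior for sigma_residual")
        if len(self.random_subject) > 1 and "rho" not in self.priors:
            raise ValueError("no prior for rho")

    @property
    def prior_set_id(self) -> str:
        parts = []
        for k in sorted(self.priors):
            p = self.priors[k]
            parts.append(f"{k}:{p.family}({p.loc},{p.scale},{p.truncation},{p.lkj_eta})")
        return "|".join(parts)


def drop_term(spec: ModelSpec, term: str) -> ModelSpec:
    """Null-model builder: remove a fixed term, keep all random effects."""
    if term not in spec.fixed_terms:
        raise ValueError(f"{term!r} not in fixed terms")
    priors = {k: v for k, v in spec.priors.items() if k != term}
    return replace(
        spec,
        fixed_terms=[t for t in spec.fixed_terms if t != term],
        priors=priors,
    )


def with_prior(spec: ModelSpec, term: str, prior: PriorSpec) -> ModelSpec:
    priors = dict(spec.priors)
    priors[term] = prior
    return replace(spec, priors=priors)


# ---------------------------------------------------------------------------
# parameter layout on the unconstrained scale


class _Layout:
    """Maps the flat unconstrained vector to natural parameters.

    Order: betas (identity or signed-exp for one-sided priors),
    log sigma_subject (q_s), atanh partial correlations, log sigma_item,
    log sigma_residual (if free).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.beta_terms = [INTERCEPT] + list(spec.fixed_terms)
        self.p = len(self.beta_terms)
        self.beta_sign = np.zeros(self.p)  # 0: identity, +1/-1: signed exp
        for j, t in enumerate(self.beta_terms):
            trunc = spec.priors[t].effective_truncation
            if trunc == "negative_only":
                self.beta_sign[j] = -1.0
            elif trunc == "positive_only":
                self.beta_sign[j] = 1.0
        self.q_s = len(spec.random_subject)
        self.nz = n_partials(self.q_s) if self.q_s > 1 else 0
        self.has_item = spec.random_item
        self.free_res = spec.sigma_residual_fixed is None
        self.d = self.p + self.q_s + self.nz + int(self.has_item) + int(self.free_res)

        names = [f"b_{t}" for t in self.beta_terms]
        names += [f"sigma_subject__{t}" for t in spec.random_subject]
        rs = spec.random_subject
        names += [f"rho__{rs[i]}__{rs[j]}" for i in range(1, self.q_s) for j in range(i)]
        if self.has_item:
            names.append("sigma_item")
        if self.free_res:
            names.append("sigma_residual")
        self.names = names

    def decode(self, xs: np.ndarray):
        """Return (beta, A, sigma_item, sigma_res, z, sigma_s, logjac)."""
        xs = np.atleast_2d(xs)
        B = xs.shape[0]
        logjac = np.zeros(B)
        pos = 0
        beta = xs[:, : self.p].copy()
        for j in range(self.p):
            s = self.beta_sign[j]
            if s != 0.0:
                u = xs[:, j]
                beta[:, j] = s * np.exp(u)
                logjac += u
        pos = self.p
        sigma_s = None
        A = None
        z = None
        if self.q_s:
            u = xs[:, pos : pos + self.q_s]
            sigma_s = np.exp(u)
            logjac += u.sum(axis=1)
            pos += self.q_s
            if self.nz:
                uz = xs[:, pos : pos + self.nz]
                z = np.tanh(uz)
                logjac += np.log1p(-(z**2)).sum(axis=1)
                pos += self.nz
                L = cholesky_from_partials(z, self.q_s)
            else:
                L = np.ones((B, 1, 1))
            A = sigma_s[:, :, None] * L
        sigma_item = None
        if self.has_item:
            u = xs[:, pos]
            sigma_item = np.exp(u)
            logjac += u
            pos += 1
        if self.free_res:
            u = xs[:, pos]
            sigma_res = np.exp(u)
            logjac += u
        else:
            sigma_res = np.full(B, float(self.spec.sigma_residual_fixed))
        return beta, A, sigma_item, sigma_res, z, sigma_s, logjac

    def log_prior(self, beta, sigma_s, z, sigma_item, sigma_res) -> np.ndarray:
        spec = self.spec
        B = beta.shape[0]
        lp = np.zeros(B)
        for j, t in enumerate(self.beta_terms):
            lp += spec.priors[t].logpdf(beta[:, j])
        if self.q_s:
            for a in range(self.q_s):
                lp += spec.priors["sigma_subject"].logpdf(sigma_s[:, a])
            if self.nz:
                lp += lkj_partials_logpdf(z, self.q_s, spec.priors["rho"].lkj_eta)
        if self.has_item:
            lp += spec.priors["sigma_item"].logpdf(sigma_item)
        if self.free_res:
            lp += spec.priors["sigma_residual"].logpdf(sigma_res)
        return lp

    def natural_draws(self, xs: np.ndarray) -> dict[str, np.ndarray]:
        """Map unconstrained draws (C, T, d) to named natural draws (C, T)."""
        C, T, d = xs.shape
        beta, A, sigma_item, sigma_res, z, sigma_s, _ = self.decode(xs.reshape(-1, d))
        out = {}
        for j, t in enumerate(self.beta_terms):
            out[f"b_{t}"] = beta[:, j].reshape(C, T)
        if self.q_s:
            for a, t in enumerate(self.spec.random_subject):
                out[f"sigma_subject__{t}"] = sigma_s[:, a].reshape(C, T)
            if self.nz:
                # report correlations (not partials) of the implied matrix
                L = cholesky_from_partials(z, self.q_s)
                R = L @ np.swapaxes(L, -1, -2)
                rs = self.spec.random_subject
                for i in range(1, self.q_s):
                    for j in range(i):
                        out[f"rho__{rs[i]}__{rs[j]}"] = R[:, i, j].reshape(C, T)
        if self.has_item:
            out["sigma_item"] = sigma_item.reshape(C, T)
        if self.free_res:
            out["sigma_residual"] = sigma_res.reshape(C, T)
        return out


# ---------------------------------------------------------------------------
# fitted posterior container


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, report: "ConvergenceReport"):
        super().__init__(message)
        self.report = report


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    passed: bool


@dataclass
class PosteriorSamples:
    """MCMC draws plus everything needed to re-evaluate the posterior."""

    draws: dict[str, np.ndarray]  # name -> (chains, iterations)
    unconstrained: np.ndarray  # (chains, iterations, d)
    log_posterior: Callable[[np.ndarray], np.ndarray]
    layout: _Layout
    lmm: CollapsedLMM
    spec: ModelSpec
    seed: int

    @property
    def n_chains(self) -> int:
        return self.unconstrained.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.unconstrained.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        C, T, _ = self.unconstrained.shape
        rows = {"chain": np.repeat(np.arange(C), T), "iteration": np.tile(np.arange(T), C)}
        for k, v in self.draws.items():
            rows[k] = v.reshape(-1)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitting


def _build_matrices(table: pd.DataFrame, spec: ModelSpec):
    if len(table) == 0:
        raise ValueError("empty trial table")
    for col in [spec.response] + list(spec.fixed_terms):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from trial table")
    y = table[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(table))] + [table[t].to_numpy(dtype=float) for t in spec.fixed_terms]
    )
    subject = Zs = item = None
    if spec.random_subject:
        if spec.subject_col not in table.columns:
            raise ValueError(f"column {spec.subject_col!r} missing from trial table")
        subject = table[spec.subject_col].to_numpy()
        cols = []
        for t in spec.random_subject:
            cols.append(
                np.ones(len(table)) if t == INTERCEPT else table[t].to_numpy(dtype=float)
            )
        Zs = np.column_stack(cols)
    if spec.random_item:
        if spec.item_col not in table.columns:
            raise ValueError(f"column {spec.item_col!r} missing from trial table")
        item = table[spec.item_col].to_numpy()
    return y, X, subject, Zs, item


def _make_log_posterior(lmm: CollapsedLMM, layout: _Layout, chunk: int = 64):
    def log_posterior(xs: np.ndarray) -> np.ndarray:
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        if xs.shape[0] > chunk:  # keep the (B, q, q) work sets cache-sized
            return np.concatenate(
                [log_posterior(xs[i : i + chunk]) for i in range(0, xs.shape[0], chunk)]
            )
        beta, A, sigma_item, sigma_res, z, sigma_s, logjac = layout.decode(xs)
        lp = layout.log_prior(beta, sigma_s, z, sigma_item, sigma_res)
        ok = np.isfinite(lp)
        out = np.full(xs.shape[0], -np.inf)
        if np.any(ok):
            ll = lmm.loglik(
                beta[ok],
                None if A is None else A[ok],
                None if sigma_item is None else sigma_item[ok],
                sigma_res[ok],
            )
            out[ok] = lp[ok] + ll + logjac[ok]
        return out

    return log_posterior


def _initial_point(layout: _Layout, lmm: CollapsedLMM, y_sd: float) -> np.ndarray:
    x0 = np.zeros(layout.d)
    ridge = lmm.XtX + np.eye(lmm.p)
    beta0 = np.linalg.solve(ridge, lmm.Xty)
    for j in range(layout.p):
        s = layout.beta_sign[j]
        if s == 0.0:
            x0[j] = beta0[j]
        else:
            x0[j] = math.log(max(abs(beta0[j]), 0.05))
    pos = layout.p
    spec = layout.spec
    if layout.q_s:
        x0[pos : pos + layout.q_s] = math.log(max(spec.priors["sigma_subject"].scale / 2, 1e-3))
        pos += layout.q_s + layout.nz
    if layout.has_item:
        x0[pos] = math.log(max(spec.priors["sigma_item"].scale / 2, 1e-3))
        pos += 1
    if layout.free_res:
        pr = spec.priors["sigma_residual"]
        x0[pos] = math.log(pr.loc if pr.loc > 0 else max(y_sd, 1e-3))
    return x0


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    d = x.size
    pts = [x]
    for i in range(d):
        for s in (+1, -1):
            e = x.copy()
            e[i] += s * h
            pts.append(e)
    for i in range(d):
        for j in range(i):
            for si, sj in ((1, 1), (-1, -1)):
                e = x.copy()
                e[i] += si * h
                e[j] += sj * h
                pts.append(e)
    vals = f(np.array(pts))
    f0 = vals[0]
    H = np.zeros((d, d))
    idx = 1 + 2 * d
    fplus = vals[1 : 1 + 2 * d : 2]
    fminus = vals[2 : 2 + 2 * d : 2]
    for i in range(d):
        H[i, i] = (fplus[i] - 2 * f0 + fminus[i]) / h**2
    for i in range(d):
        for j in range(i):
            fpp, fmm = vals[idx], vals[idx + 1]
            idx += 2
            H[i, j] = H[j, i] = (
                fpp + fmm - 2 * f0 - H[i, i] * h**2 - H[j, j] * h**2
            ) / (2 * h**2)
    return H


def _proposal_cov(H: np.ndarray) -> np.ndarray:
    # negative Hessian of the log posterior -> covariance, eigenvalue-clipped
    d = H.shape[0]
    Hn = -0.5 * (H + H.T)
    try:
        w, V = np.linalg.eigh(Hn)
    except np.linalg.LinAlgError:
        return np.eye(d) * 0.1
    w = np.clip(w, 1e-4, None)
    return (V / w) @ V.T


def fit_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    chains: int = 4,
    iterations: int = 2000,
    warmup: int = 1000,
    seed: int = 0,
    *,
    adapt_interval: int = 50,
    target_accept: float = 0.234,
    check: tuple[float, float] | None = None,
    _retry: bool = True,
) -> PosteriorSamples:
    """Fit the model by adaptive random-walk Metropolis on the collapsed posterior.

    The default desk-scale settings (4 chains x 1,000 post-warmup draws) are
    a documented reduction of the registered 50,000-iteration contract; pass
    larger ``iterations`` to approach it. ``check`` optionally enforces
    ``(rhat_max, ess_min)``; on failure the fit is retried once with doubled
    iterations before raising :class:`ConvergenceError`.
    """
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    y, X, subject, Zs, item = _build_matrices(table, spec)
    lmm = CollapsedLMM(y, X, subject, Zs, item)
    layout = _Layout(spec)
    log_post = _make_log_posterior(lmm, layout)

    rng = np.random.default_rng(seed)
    x0 = _initial_point(layout, lmm, float(np.std(y)))

    def neg_post_and_grad(x, h=1e-5):
        pts = np.vstack([x[None], x[None] + h * np.eye(layout.d), x[None] - h * np.eye(layout.d)])
        vals = log_post(pts)
        # perturbations can step outside the support; treat as steeply downhill
        finite = np.isfinite(vals)
        floor = (vals[finite].min() if finite.any() else 0.0) - 1e6
        vals = np.where(finite, vals, floor)
        grad = -(vals[1 : 1 + layout.d] - vals[1 + layout.d :]) / (2 * h)
        return -vals[0], grad

    res = optimize.minimize(
        neg_post_and_grad, x0, jac=True, method="L-BFGS-B", options={"maxiter": 200}
    )
    mode = res.x
    cov0 = _proposal_cov(_numeric_hessian(log_post, mode))

    xs = mode[None, :] + rng.standard_normal((chains, layout.d)) @ np.linalg.cholesky(
        cov0 + 1e-12 * np.eye(layout.d)
    ).T * 0.3
    fx = log_post(xs)
    bad = ~np.isfinite(fx)
    if np.any(bad):
        xs[bad] = mode
        fx[bad] = log_post(mode[None])[0]

    d = layout.d
    log_scale = math.log(2.38 / math.sqrt(d))
    Lprop = np.linalg.cholesky(cov0 + 1e-12 * np.eye(d))
    history: list[np.ndarray] = []

    def step(xs, fx, adapt: bool):
        nonlocal log_scale, Lprop
        prop = xs + (rng.standard_normal((chains, d)) @ Lprop.T) * math.exp(log_scale)
        fp = log_post(prop)
        accept = np.log(rng.uniform(size=chains)) < fp - fx
        xs = np.where(accept[:, None], prop, xs)
        fx = np.where(accept, fp, fx)
        if adapt:
            log_scale += 0.05 * (accept.mean() - target_accept)
        return xs, fx

    for t in range(warmup):
        xs, fx = step(xs, fx, adapt=True)
        history.append(xs.copy())
        if t >= adapt_interval and t % adapt_interval == 0:
            states = np.concatenate(history[len(history) // 2 :], axis=0)
            if len(states) > 2 * d:
                emp = np.cov(states.T) + 1e-10 * np.eye(d)
                try:
                    Lprop = np.linalg.cholesky(emp)
                except np.linalg.LinAlgError:
                    pass

    draws = np.empty((chains, iterations, d))
    for t in range(iterations):
        xs, fx = step(xs, fx, adapt=False)
        draws[:, t] = xs

    samples = PosteriorSamples(
        draws=layout.natural_draws(draws),
        unconstrained=draws,
        log_posterior=log_post,
        layout=layout,
        lmm=lmm,
        spec=spec,
        seed=seed,
    )
    if check is not None:
        rhat_max, ess_min = check
        report = check_convergence(samples, rhat_max=rhat_max, ess_min=ess_min)
        if not report.passed:
            if _retry:
                return fit_model(
                    table, spec, chains, iterations * 2, warmup * 2, seed + 1,
                    adapt_interval=adapt_interval, target_accept=target_accept,
                    check=check, _retry=False,
                )
            raise ConvergenceError("model did not converge after retry", report)
    return samples


# ---------------------------------------------------------------------------
# diagnostics and summaries


def check_convergence(
    samples: PosteriorSamples, rhat_max: float = 1.01, ess_min: float = 2000
) -> ConvergenceReport:
    """Per-parameter split-R-hat and bulk/tail ESS verdicts (via arviz)."""
    import arviz as az

    idata = az.from_dict(posterior={k: v for k, v in samples.draws.items()})
    rhat = az.rhat(idata)
    ess_bulk = az.ess(idata, method="bulk")
    ess_tail = az.ess(idata, method="tail")
    rows = []
    for name in samples.draws:
        r = float(rhat[name].values)
        eb = float(ess_bulk[name].values)
        et = float(ess_tail[name].values)
        rows.append(
            {
                "parameter": name,
                "rhat": r,
                "ess_bulk": eb,
                "ess_tail": et,
                "passed": bool(r <= rhat_max and eb >= ess_min and et >= ess_min),
            }
        )
    tab = pd.DataFrame(rows)
    return ConvergenceReport(table=tab, passed=bool(tab["passed"].all()))


def summarize_posterior(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central quantile interval (linear interpolation)."""
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for name, v in samples.draws.items():
        flat = v.reshape(-1)
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "lower": float(np.quantile(flat, lo_q)),
                "upper": float(np.quantile(flat, hi_q)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# prior predictive


def prior_predictive(
    spec: ModelSpec, design: pd.DataFrame, seed: int = 0, n_draws: int = 200
) -> dict:
    """Draw parameters from the priors, then data from the likelihood.

    ``design`` must contain the predictor columns plus subject/item ids.
    Returns parameter draws and an (n_draws, n_trials) amplitude array.
    """
    rng = np.random.default_rng(seed)
    y_placeholder = np.zeros(len(design))
    tab = design.copy()
    tab[spec.response] = y_placeholder
    _, X, subject, Zs, item = _build_matrices(tab, spec)
    layout = _Layout(spec)
    n = len(design)

    betas = np.empty((n_draws, layout.p))
    for j, t in enumerate(layout.beta_terms):
        betas[:, j] = spec.priors[t].rvs(rng, size=n_draws)
    amps = np.empty((n_draws, n))
    params: dict[str, np.ndarray] = {
        f"b_{t}": betas[:, j] for j, t in enumerate(layout.beta_terms)
    }
    sigma_res = (
        np.full(n_draws, spec.sigma_residual_fixed)
        if spec.sigma_residual_fixed is not None
        else spec.priors["sigma_residual"].rvs(rng, size=n_draws)
    )
    params["sigma_residual"] = sigma_res
    if layout.q_s:
        sigma_s = spec.priors["sigma_subject"].rvs(rng, size=(n_draws, layout.q_s))
        params.update(
            {f"sigma_subject__{t}": sigma_s[:, a] for a, t in enumerate(spec.random_subject)}
        )
        if layout.nz:
            zs = sample_partials(rng, layout.q_s, spec.priors["rho"].lkj_eta, size=n_draws)
            Ls = cholesky_from_partials(zs, layout.q_s)
        else:
            Ls = np.ones((n_draws, 1, 1))
    if layout.has_item:
        sigma_i = spec.priors["sigma_item"].rvs(rng, size=n_draws)
        params["sigma_item"] = sigma_i
        icodes = pd.factorize(tab[spec.item_col])[0]
    if layout.q_s:
        scodes = pd.factorize(tab[spec.subject_col])[0]
        S = scodes.max() + 1
    for k in range(n_draws):
        mu = X @ betas[k]
        if layout.q_s:
            A = sigma_s[k][:, None] * Ls[k]
            u = rng.standard_normal((S, layout.q_s)) @ A.T
            mu = mu + np.einsum("na,na->n", Zs, u[scodes])
        if layout.has_item:
            w = rng.normal(0.0, sigma_i[k], size=icodes.max() + 1)
            mu = mu + w[icodes]
        amps[k] = mu + rng.normal(0.0, sigma_res[k], size=n)
    return {"parameters": params, "amplitude": amps}
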