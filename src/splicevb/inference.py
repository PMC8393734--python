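"""Variational inference for logit-normal splicing ratios.

The prior on z = logit(psi) is a Gaussian regression on gene features X and
cell covariates Y with event-level dispersion sigma_g; the variational
posterior is a fully factorised Gaussian N(mu_cg, delta_cg^2).  The ELBO

    ELBO = -KL(q || prior) + E_q[log p(counts | z)]

is maximised by Adam on an unbiased R-sample Monte-Carlo estimate of the
likelihood term via the reparameterisation trick, with analytic gradients
(no autodiff framework required).  The KL term is closed form.

Usage modes
-----------
``mode0``        no features; fixed N(0, prior0_scale^2) prior.
``mode1``        gene features X; cell-specific weights A are fitted.
``mode2_quant``  intercept-only cell covariate (adaptive per-event prior).
``mode2_diff``   cell covariates Y for differential testing.

Dispersions sigma_g are optimised as free hyperparameters (empirical
Bayes) in every mode except mode0, independently in each fitted model.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import expit

from .core_data import (
    FeatureMatrices,
    SplicingCountData,
    ValidationError,
    intercept_features,
)
from .likelihood import loglik_and_grad_z, loglik_from_z

__all__ = [
    "FitConfig",
    "ModelParams",
    "VariationalPosterior",
    "FitResult",
    "PsiSummary",
    "prior_params",
    "kl_gaussian",
    "elbo_estimate",
    "fit",
    "psi_summarise",
]

MODES = ("mode0", "mode1", "mode2_quant", "mode2_diff")

_DELTA_FLOOR = 1e-6
_EVAL_STREAM = 0xE7A1  # sub-seed tag for the final-ELBO evaluation stream


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    y = np.asarray(y, dtype=float)
    return np.where(y > 30, y, np.log(np.expm1(np.minimum(y, 30.0))))


@dataclasses.dataclass
class FitConfig:
    """Optimisation settings for :func:`fit`."""

    mode: str = "mode2_quant"
    R: int = 3
    R_eval: int = 500
    learning_rate: float = 0.05
    max_iter: int = 5000
    rel_tol: float = 1e-4
    window: int = 100
    seed: int = 0
    sigma_min: float = 1e-2
    prior0_scale: float = 3.0
    l2_weight: float = 1e-4

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.R < 1 or self.R_eval < self.R:
            raise ValidationError("need R >= 1 and R_eval >= R")
        if min(self.learning_rate, self.sigma_min, self.prior0_scale) <= 0:
            raise ValidationError("learning_rate, sigma_min, prior0_scale must be > 0")
        if self.max_iter < 1 or self.window < 1 or self.rel_tol < 0:
            raise ValidationError("invalid iteration/convergence settings")


@dataclasses.dataclass
class ModelParams:
    """Regression weights and dispersions of the prior."""

    A: np.ndarray  # (M, D) cell-specific weights on gene features
    B: np.ndarray  # (N, K) event-specific weights on cell covariates
    sigma: np.ndarray  # (N,) event-level prior std

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValidationError("sigma must be positive")


@dataclasses.dataclass
class VariationalPosterior:
    """Factorised Gaussian posterior over logit-PSI: N(mu, delta^2)."""

    mu: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.mu.shape != self.delta.shape:
            raise ValidationError("mu and delta must share a shape")
        if np.any(self.delta <= 0):
            raise ValidationError("delta must be positive")


@dataclasses.dataclass
class FitResult:
    params: ModelParams
    posterior: VariationalPosterior
    elbo_trace: np.ndarray
    final_elbo: float
    final_elbo_se: float
    per_event_elbo: np.ndarray
    per_event_elbo_se: np.ndarray
    converged: bool
    n_iter: int
    config: FitConfig


@dataclasses.dataclass
class PsiSummary:
    psi_median: np.ndarray
    psi_mean: np.ndarray
    psi_ci_low: np.ndarray
    psi_ci_high: np.ndarray
    ci_level: float


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def prior_params(
    X: np.ndarray | None,
    Y: np.ndarray | None,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(cell, event) prior mean matrix and per-event prior std.

    ``mean[c, g] = A[c] . X[g] + Y[c] . B[g]``; absent feature blocks
    (``None`` or zero columns) contribute nothing.
    """
    M = params.A.shape[0]  # A is always (M, D), B always (N, K), even at D/K = 0
    N = params.B.shape[0]
    mean = np.zeros((M, N))
    if X is not None and X.shape[1] > 0:
        X = np.asarray(X, dtype=float)
        if params.A.shape[1] != X.shape[1] or X.shape[0] != N:
            raise ValidationError(
                f"gene-feature shapes inconsistent: X {X.shape}, A {params.A.shape}"
            )
        mean = mean + params.A @ X.T
    if Y is not None and Y.shape[1] > 0:
        Y = np.asarray(Y, dtype=float)
        if params.B.shape[1] != Y.shape[1] or Y.shape[0] != M:
            raise ValidationError(
                f"cell-covariate shapes inconsistent: Y {Y.shape}, B {params.B.shape}"
            )
        mean = mean + Y @ params.B.T
    if params.sigma.shape != (N,):
        raise ValidationError("sigma must have one entry per event")
    return mean, params.sigma


def kl_gaussian(mu_q, delta_q, mu_p, sigma_p, *, elementwise: bool = False):
    """KL( N(mu_q, delta_q^2) || N(mu_p, sigma_p^2) ), summed over elements.

    Closed form: ``log(sigma_p/delta_q) + (delta_q^2 + (mu_q - mu_p)^2) /
    (2 sigma_p^2) - 1/2``.
    """
    delta_q = np.asarray(delta_q, dtype=float)
    sigma_p = np.asarray(sigma_p, dtype=float)
    if np.any(delta_q <= 0) or np.any(sigma_p <= 0):
        raise ValidationError("scales must be positive")
    mu_q = np.asarray(mu_q, dtype=float)
    mu_p = np.asarray(mu_p, dtype=float)
    kl = (
        np.log(sigma_p / delta_q)
        + (delta_q**2 + (mu_q - mu_p) ** 2) / (2.0 * sigma_p**2)
        - 0.5
    )
    if elementwise:
        return kl
    return float(np.sum(kl))


def elbo_estimate(
    data: SplicingCountData,
    X: np.ndarray | None,
    Y: np.ndarray | None,
    params: ModelParams,
    posterior: VariationalPosterior,
    R: int,
    rng: np.random.Generator,
) -> float:
    """Unbiased R-sample Monte-Carlo ELBO estimate (reparameterisation trick)."""
    if R < 1:
        raise ValidationError("R must be >= 1")
    mean, sigma = prior_params(X, Y, params)
    mu, delta = posterior.mu, posterior.delta
    kl = kl_gaussian(mu, delta, mean, sigma[None, :])
    eps = rng.standard_normal((R,) + mu.shape)
    z = mu + delta * eps
    ll = loglik_from_z(z, data.counts, data.lengths)
    return float(ll.sum(axis=(1, 2)).mean() - kl)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class _Adam:
    """Element-wise Adam ascent over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] += self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _resolve_features(
    data: SplicingCountData,
    features: FeatureMatrices | None,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (X, Y, y_names) as demanded by the usage mode."""
    M, N = data.n_cells, data.n_events
    if config.mode == "mode0":
        return np.zeros((N, 0)), np.zeros((M, 0)), []
    if config.mode == "mode1":
        if features is None or features.X.shape[1] == 0:
            raise ValidationError("mode1 requires gene features X")
        if features.X.shape[0] != N:
            raise ValidationError("X rows must match events")
        return features.X, np.zeros((M, 0)), []
    if config.mode == "mode2_quant":
        feats = features or intercept_features(data.cell_ids, N)
        if feats.Y.shape != (M, 1) or not feats.is_intercept_column(0):
            raise ValidationError("mode2_quant requires an intercept-only Y")
        return np.zeros((N, 0)), feats.Y, list(feats.y_names)
    # mode2_diff
    if features is None or features.Y.shape[1] == 0:
        raise ValidationError("mode2_diff requires cell covariates Y")
    if features.Y.shape[0] != M:
        raise ValidationError("Y rows must match cells")
    return features.X, features.Y, list(features.y_names)


def _init_mu(data: SplicingCountData) -> np.ndarray:
    """Empirical logit estimate from unique reads, clipped to [-3, 3]."""
    s1 = data.counts[:, :, 0].astype(float)
    s2 = data.counts[:, :, 1].astype(float)
    psi0 = (s1 + 1.0) / (s1 + s2 + 2.0)
    return np.clip(np.log(psi0 / (1.0 - psi0)), -3.0, 3.0)


def fit(
    data: SplicingCountData,
    features: FeatureMatrices | None = None,
    config: FitConfig | None = None,
    fixed_zero: tuple[str, ...] = (),
) -> FitResult:
    """Maximise the Monte-Carlo ELBO over posterior and prior parameters.

    ``fixed_zero`` names cell-covariate columns whose regression weights are
    clamped to zero (the nested model of a differential test); all other
    columns are retained.  Runs are deterministic given ``config.seed``; the
    final ELBO is evaluated with ``R_eval`` common-random-number samples so
    that ELBO differences between nested fits have low Monte-Carlo noise.

    Notes
    -----
    Per iteration a single noise draw of shape ``(R, n_cells, 1)`` is shared
    across events.  Each event's MC gradient stays unbiased (events are
    conditionally independent), and per-event optimisation paths become
    independent of which other events are present in the dataset.
    """
    config = config or FitConfig()
    M, N = data.n_cells, data.n_events
    X, Y, y_names = _resolve_features(data, features, config)
    D, K = X.shape[1], Y.shape[1]

    bmask = np.ones((N, K))
    for name in fixed_zero:
        if name not in y_names:
            raise ValidationError(f"fixed_zero column {name!r} not among covariates")
        bmask[:, y_names.index(name)] = 0.0

    S = data.counts.astype(float)
    lengths = data.lengths
    mode0 = config.mode == "mode0"

    # parameter initialisation (shared by nested model pairs)
    if mode0:
        mu = np.zeros((M, N))
        delta0 = config.prior0_scale
    else:
        mu = _init_mu(data)
        delta0 = 1.0
    draw = np.full((M, N), _inv_softplus(delta0 - _DELTA_FLOOR))
    A = np.zeros((M, D))
    B = np.zeros((N, K))
    sraw = np.full(N, _inv_softplus(max(1.0 - config.sigma_min, 1e-3)))

    params = {"mu": mu, "draw": draw}
    if not mode0:
        params["sraw"] = sraw
    if D:
        params["A"] = A
    if K:
        params["B"] = B
    opt = _Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    lam = config.l2_weight

    trace = np.empty(config.max_iter)
    converged = False
    n_iter = config.max_iter
    w = config.window

    for it in range(config.max_iter):
        mu = params["mu"]
        delta = _softplus(params["draw"]) + _DELTA_FLOOR
        if mode0:
            sigma = np.full(N, config.prior0_scale)
            m_prior = np.zeros((M, N))
        else:
            sigma = config.sigma_min + _softplus(params["sraw"])
            m_prior = np.zeros((M, N))
            if D:
                m_prior = m_prior + params["A"] @ X.T
            if K:
                m_prior = m_prior + Y @ (params["B"] * bmask).T

        eps = rng.standard_normal((config.R, M, 1))
        z = mu + delta * eps
        ll, gz = loglik_and_grad_z(z, S, lengths)

        sig2 = sigma**2
        diff = mu - m_prior
        kl = np.log(sigma / delta) + (delta**2 + diff**2) / (2.0 * sig2) - 0.5
        elbo = ll.sum(axis=(1, 2)).mean() - kl.sum()
        trace[it] = elbo
        if not np.isfinite(elbo):
            g_bad = int(np.argmax(~np.isfinite(kl).all(axis=0))) if not np.isfinite(kl).all() else -1
            raise FloatingPointError(
                f"ELBO diverged at iteration {it} (event index {g_bad})"
            )

        gmu = gz.mean(axis=0) - diff / sig2
        gdelta = (gz * eps).mean(axis=0) + 1.0 / delta - delta / sig2
        grads = {
            "mu": gmu,
            "draw": gdelta * expit(params["draw"]),
        }
        if not mode0:
            gsigma = ((delta**2 + diff**2) / sigma**3 - 1.0 / sigma).sum(axis=0)
            grads["sraw"] = gsigma * expit(params["sraw"])
        gm = diff / sig2  # dELBO / d prior-mean
        if D:
            grads["A"] = gm @ X - 2.0 * lam * params["A"]
        if K:
            grads["B"] = (gm.T @ Y - 2.0 * lam * params["B"]) * bmask
        opt.step(params, grads)

        if (it + 1) >= 2 * w and (it + 1) % w == 0:
            recent = trace[it + 1 - w: it + 1].mean()
            prev = trace[it + 1 - 2 * w: it + 1 - w].mean()
            if abs(recent - prev) / max(abs(prev), 1.0) < config.rel_tol:
                converged = True
                n_iter = it + 1
                break

    mu = params["mu"].copy()
    delta = _softplus(params["draw"]) + _DELTA_FLOOR
    if mode0:
        sigma = np.full(N, config.prior0_scale)
        m_prior = np.zeros((M, N))
    else:
        sigma = config.sigma_min + _softplus(params["sraw"])
        m_prior = np.zeros((M, N))
        if D:
            m_prior = m_prior + params["A"] @ X.T
        if K:
            m_prior = m_prior + Y @ (params["B"] * bmask).T

    kl_g = kl_gaussian(mu, delta, m_prior, sigma[None, :], elementwise=True).sum(axis=0)

    # final ELBO: R_eval common-random-number samples, fixed evaluation stream
    rng_eval = np.random.default_rng([config.seed, _EVAL_STREAM])
    sum_g = np.zeros(N)
    sumsq_g = np.zeros(N)
    sum_tot = 0.0
    sumsq_tot = 0.0
    done = 0
    while done < config.R_eval:
        chunk = min(10, config.R_eval - done)
        eps = rng_eval.standard_normal((chunk, M, 1))
        ll = loglik_from_z(mu + delta * eps, S, lengths)  # (chunk, M, N)
        ll_g = ll.sum(axis=1)
        sum_g += ll_g.sum(axis=0)
        sumsq_g += (ll_g**2).sum(axis=0)
        tot = ll_g.sum(axis=1)
        sum_tot += tot.sum()
        sumsq_tot += (tot**2).sum()
        done += chunk
    Re = config.R_eval
    mean_g = sum_g / Re
    var_g = np.maximum(sumsq_g / Re - mean_g**2, 0.0)
    per_event_elbo = mean_g - kl_g
    per_event_se = np.sqrt(var_g / Re)
    mean_tot = sum_tot / Re
    var_tot = max(sumsq_tot / Re - mean_tot**2, 0.0)
    final_elbo = float(mean_tot - kl_g.sum())
    final_se = float(np.sqrt(var_tot / Re))

    result = FitResult(
        params=ModelParams(
            A=params.get("A", np.zeros((M, 0))),
            B=params.get("B", np.zeros((N, 0))) * (bmask if K else 1.0),
            sigma=sigma,
        ),
        posterior=VariationalPosterior(mu=mu, delta=delta),
        elbo_trace=trace[: it + 1].copy(),
        final_elbo=final_elbo,
        final_elbo_se=final_se,
        per_event_elbo=per_event_elbo,
        per_event_elbo_se=per_event_se,
        converged=converged,
        n_iter=n_iter if converged else it + 1,
        config=config,
    )
    if not converged and config.rel_tol > 0:
        warnings.warn(
            f"fit reached max_iter={config.max_iter} without meeting rel_tol",
            stacklevel=2,
        )
    return result


def psi_summarise(
    result: FitResult,
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> PsiSummary:
    """Posterior summaries of psi from the fitted logit-normal posterior.

    The median is ``logistic(mu)`` exactly; the credible interval maps
    Gaussian quantiles through the logistic; the mean is a Monte-Carlo
    estimate over ``n_samples`` draws (seed-deterministic via ``rng``).
    """
    from scipy.stats import norm

    rng = rng or np.random.default_rng(0)
    mu, delta = result.posterior.mu, result.posterior.delta
    zq = norm.ppf(0.5 + ci_level / 2.0)
    acc = np.zeros_like(mu)
    for _ in range(n_samples):
        acc += expit(mu + delta * rng.standard_normal(mu.shape))
    return PsiSummary(
        psi_median=expit(mu),
        psi_mean=acc / n_samples,
        psi_ci_low=expit(mu - zq * delta),
        psi_ci_high=expit(mu + zq * delta),
        ci_level=ci_level,
    )
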