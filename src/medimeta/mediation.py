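"""Bayesian three-variable causal mediation model.

The model decomposes the total effect of a two-arm intervention on a
behavioural outcome Y into the part transmitted through the mediator M
(hippocampal neurogenesis) and the part acting through every other
mechanism.  With T the 0/1 treatment indicator it consists of two normal
linear regressions::

    M = alpha_M + beta1 * T + eps_M,   eps_M ~ N(0, sigma_M^2)
    Y = alpha_Y + beta3 * M + beta4 * T + eps_Y,   eps_Y ~ N(0, sigma_Y^2)

The *indirect* (mediated) effect is the product of path coefficients
beta1 * beta3, the *direct* effect is beta4, and the *total* effect is
their sum.  Working with posterior draws makes the distribution of the
product -- which is not normal in small samples -- available exactly, so
the 95% credible interval of the indirect effect needs no delta-method
approximation.

Sampling.  Under a flat prior on the coefficients and p(sigma^2) ~ 1/sigma^2,
each regression has a closed-form normal--inverse-gamma posterior, so the
default sampler draws independent exact samples ("conjugate" method):
sigma^2 is drawn from its marginal scaled-inverse-chi-square and the
coefficients from their conditional multivariate normal.  A conventional
Gibbs sampler ("gibbs" method) is also provided; it supports a weakly
informative normal prior on coefficients with an inverse-gamma(0.001, 0.001)
prior on the error variances, and honours burn-in and thinning.  Posterior
means of the coefficients coincide with the least-squares estimates under
the flat prior, which the test-suite exploits as an oracle.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import Orientation, StandardizedStudy
from .errors import (
    ConsistencyError,
    DegenerateDataError,
    DesignError,
    DomainError,
    PrecisionError,
)

__all__ = [
    "Prior",
    "MediationConfig",
    "MediationPosterior",
    "EffectEstimate",
    "fit_mediation",
    "indirect_draws",
    "summarize_effect",
    "percent_mediated",
    "gelman_rubin",
    "orient_effects",
    "effect_estimate",
]

COEF_PARAMS = ("alpha_m", "beta1", "sigma_m", "alpha_y", "beta3", "beta4", "sigma_y")
RHAT_THRESHOLD = 1.01


class Prior(str, enum.Enum):
    FLAT = "flat"
    WEAK_NORMAL = "weak_normal"


@dataclass(frozen=True)
class MediationConfig:
    """Sampler settings.

    Defaults are desk-scale: 3 chains x 20,000 retained draws of the exact
    conjugate sampler, which draws independent samples so burn-in and
    thinning are unnecessary (they are honoured by the ``gibbs`` method).
    The long protocol used with generic Gibbs samplers (3 chains of 10^6
    iterations, burn-in 5000, thin 10) can be requested explicitly.

    ``weak_normal_sd`` is the prior standard deviation of the coefficients
    under the weakly informative prior; the error variances then get an
    inverse-gamma(0.001, 0.001) prior.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 0
    thin: int = 1
    seed: int = 0
    prior: Prior = Prior.FLAT
    method: str = "conjugate"  # "conjugate" | "gibbs"
    weak_normal_sd: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "prior", Prior(self.prior))
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise DomainError("n_chains, n_iter, thin must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise DomainError("need 0 <= burn_in < n_iter")
        if self.method not in ("conjugate", "gibbs"):
            raise DomainError(f"unknown sampler method {self.method!r}")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class MediationPosterior:
    """Joint posterior draws for one study.

    ``draws`` maps parameter name to a (n_chains, n_retained) array.  The
    derived ``indirect`` (beta1*beta3), ``direct`` (beta4) and ``total``
    (beta4 + beta1*beta3) draws are exposed flattened across chains, which
    is the form the study-level effect summaries use.
    """

    draws: dict[str, np.ndarray]
    study_id: str = ""
    sign_flipped: bool = False
    converged: bool | None = None

    def chain_draws(self, param: str) -> np.ndarray:
        return self.draws[param]

    def flat(self, param: str) -> np.ndarray:
        return self.draws[param].ravel()

    @property
    def indirect(self) -> np.ndarray:
        return indirect_draws(self)

    @property
    def direct(self) -> np.ndarray:
        return self.flat("beta4")

    @property
    def total(self) -> np.ndarray:
        return self.indirect + self.direct

    @property
    def n_draws(self) -> int:
        return self.draws["beta1"].size

    @property
    def rhat(self) -> dict[str, float]:
        """Gelman-Rubin statistic per parameter (needs >=2 chains)."""
        return {p: gelman_rubin(self.draws[p]) for p in self.draws}

    def summaries(self) -> dict[str, dict[str, float]]:
        out = {p: summarize_effect(self.flat(p)) for p in self.draws}
        out["indirect"] = summarize_effect(self.indirect)
        out["direct"] = summarize_effect(self.direct)
        out["total"] = summarize_effect(self.total)
        return out


@dataclass(frozen=True)
class EffectEstimate:
    """A study-level standardised effect, ready for meta-analytic pooling.

    ``y`` is the posterior mean, ``v`` the posterior variance (the squared
    standard error fed to the meta-analysis), and the credible limits are
    equal-tailed 95% from posterior percentiles.
    """

    study_id: str
    quantity: str  # "indirect" | "direct"
    y: float
    v: float
    ci_low: float
    ci_high: float
    sign_flipped: bool = False
    outcome: str = ""

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise DomainError(f"posterior variance must be positive, got {self.v}")
        if not (self.ci_low <= self.y <= self.ci_high):
            raise DomainError("credible interval must bracket the posterior mean")


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with Gram matrix; raises on a singular design."""
    XtX = X.T @ X
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more observations ({n}) than parameters ({p})")
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateDataError(
            "design matrix is (near-)singular; the mediator may be constant "
            "within groups or perfectly collinear with treatment"
        )
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    return beta, XtX_inv, ssr


def _sample_regression_conjugate(X, y, n_draws, rng):
    """Exact posterior draws for a linear regression under the flat prior.

    sigma^2 | y  ~  SSR / chi2(n - p);   beta | sigma^2, y  ~  N(bhat, sigma^2 (X'X)^-1).
    """
    n, p = X.shape
    beta_hat, XtX_inv, ssr = _ols(X, y)
    if ssr <= 0:
        raise DegenerateDataError("zero residual variance: posterior is degenerate")
    sigma2 = ssr / rng.chisquare(n - p, size=n_draws)
    L = np.linalg.cholesky(XtX_inv)
    z = rng.standard_normal((n_draws, p))
    betas = beta_hat[None, :] + np.sqrt(sigma2)[:, None] * (z @ L.T)
    return betas, np.sqrt(sigma2)


def _sample_regression_gibbs(X, y, n_iter, burn_in, thin, rng, prior, prior_sd, ig_a=0.001, ig_b=0.001):
    """Gibbs sampler alternating beta | sigma^2 and sigma^2 | beta.

    With the flat prior this targets the same posterior as the conjugate
    sampler (useful as an internal cross-check); with ``weak_normal`` the
    coefficients get independent N(0, prior_sd^2) priors and sigma^2 an
    inverse-gamma(ig_a, ig_b) prior.
    """
    n, p = X.shape
    beta_hat, XtX_inv, ssr = _ols(X, y)
    XtX = X.T @ X
    Xty = X.T @ y
    sigma2 = max(ssr / max(n - p, 1), 1e-12)
    keep_beta, keep_sigma = [], []
    for it in range(n_iter):
        if prior is Prior.FLAT:
            cov = sigma2 * XtX_inv
            mean = beta_hat
        else:
            prec = XtX / sigma2 + np.eye(p) / prior_sd**2
            cov = np.linalg.inv(prec)
            mean = cov @ (Xty / sigma2)
        beta = rng.multivariate_normal(mean, cov, method="cholesky")
        resid = y - X @ beta
        rss = float(resid @ resid)
        if prior is Prior.FLAT:
            sigma2 = 1.0 / rng.gamma(n / 2.0, 2.0 / rss)
        else:
            sigma2 = 1.0 / rng.gamma(ig_a + n / 2.0, 1.0 / (ig_b + rss / 2.0))
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_beta.append(beta)
            keep_sigma.append(np.sqrt(sigma2))
    return np.array(keep_beta), np.array(keep_sigma)


def fit_mediation(
    study: StandardizedStudy, config: MediationConfig | None = None
) -> MediationPosterior:
    """Fit the mediation model and return joint posterior draws.

    Each chain gets an independent random stream derived from
    ``config.seed``.  When at least two chains are run, the Gelman-Rubin
    statistic is computed for every parameter; values above 1.01 set
    ``converged=False`` and emit a warning rather than raising, so a long
    pipeline run is not aborted by a single poorly mixing study.
    """
    config = config or MediationConfig()
    T, M, Y = study.T, study.M, study.Y
    n = study.n
    sizes = [int((T == t).sum()) for t in (0, 1)]
    if min(sizes) < 3:
        raise DesignError(f"need >=3 animals per group, got sizes {sizes}")

    X_med = np.column_stack([np.ones(n), T])
    X_out = np.column_stack([np.ones(n), M, T])
    n_keep = config.retained_per_chain
    if n_keep < 1:
        raise DomainError("sampler settings retain no draws")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    per_chain: dict[str, list[np.ndarray]] = {p: [] for p in COEF_PARAMS}
    for ss in seeds:
        rng = np.random.default_rng(ss)
        if config.method == "conjugate":
            if config.prior is not Prior.FLAT:
                raise DomainError(
                    "the conjugate sampler supports the flat prior; use "
                    "method='gibbs' for weak_normal"
                )
            bm, sm = _sample_regression_conjugate(X_med, M, n_keep, rng)
            bo, so = _sample_regression_conjugate(X_out, Y, n_keep, rng)
        else:
            bm, sm = _sample_regression_gibbs(
                X_med, M, config.n_iter, config.burn_in, config.thin, rng,
                config.prior, config.weak_normal_sd,
            )
            bo, so = _sample_regression_gibbs(
                X_out, Y, config.n_iter, config.burn_in, config.thin, rng,
                config.prior, config.weak_normal_sd,
            )
        per_chain["alpha_m"].append(bm[:, 0])
        per_chain["beta1"].append(bm[:, 1])
        per_chain["sigma_m"].append(sm)
        per_chain["alpha_y"].append(bo[:, 0])
        per_chain["beta3"].append(bo[:, 1])
        per_chain["beta4"].append(bo[:, 2])
        per_chain["sigma_y"].append(so)

    draws = {p: np.vstack(v) for p, v in per_chain.items()}
    post = MediationPosterior(draws=draws, study_id=study.meta.study_id)
    if config.n_chains >= 2:
        worst = max(post.rhat.values())
        post.converged = bool(worst <= RHAT_THRESHOLD)
        if not post.converged:
            warnings.warn(
                f"study {study.meta.study_id!r}: max Gelman-Rubin statistic "
                f"{worst:.4f} exceeds {RHAT_THRESHOLD}; treat estimates with care",
                stacklevel=2,
            )
    return post


def indirect_draws(posterior: MediationPosterior) -> np.ndarray:
    """Draws of the mediated effect: elementwise product beta1 * beta3.

    Chain alignment is preserved, so the product is itself a valid joint
    posterior sample of the indirect effect.
    """
    b1 = posterior.draws["beta1"]
    b3 = posterior.draws["beta3"]
    if b1.shape != b3.shape:
        raise ConsistencyError(
            f"misaligned draws: beta1 {b1.shape} vs beta3 {b3.shape}"
        )
    return (b1 * b3).ravel()


def summarize_effect(draws, min_draws: int = 100) -> dict[str, float]:
    """Mean, SD and equal-tailed 2.5/50/97.5 empirical percentiles of draws."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < min_draws:
        raise PrecisionError(
            f"need >= {min_draws} retained draws to summarise, got {x.size}"
        )
    q = np.percentile(x, [2.5, 50.0, 97.5])
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "q2.5": float(q[0]),
        "median": float(q[1]),
        "q97.5": float(q[2]),
    }


def percent_mediated(indirect_mean: float, direct_mean: float) -> float:
    """Percent of the total effect transmitted through the mediator.

    100 * indirect / (indirect + direct).  When the two components have
    opposite signs (inconsistent mediation / suppression) the proportion
    is not a percentage of a larger whole; it is still returned, with a
    warning, because it remains the conventional summary.
    """
    total = indirect_mean + direct_mean
    if total == 0:
        raise DomainError("total effect is zero; percent mediated is undefined")
    if indirect_mean * direct_mean < 0:
        warnings.warn(
            "indirect and direct effects have opposite signs (suppression); "
            "the percent-mediated summary can exceed [0, 100]",
            stacklevel=2,
        )
    return 100.0 * indirect_mean / total


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R-hat for >=2 aligned chains.

    R-hat = sqrt( ((n-1)/n * W + B/n) / W ) with W the mean within-chain
    sample variance and B = n * variance of the chain means (both with the
    n-1 denominator).  Values near 1 indicate that the chains are sampling
    the same distribution.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise DesignError("gelman_rubin needs >=2 chains of equal length")
    m, n = arr.shape
    if n < 2:
        raise DesignError("chains must contain >=2 draws")
    W = arr.var(axis=1, ddof=1).mean()
    if W == 0:
        raise DegenerateDataError("zero within-chain variance: R-hat undefined")
    B = n * arr.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def orient_effects(
    posterior: MediationPosterior, orientation: Orientation
) -> MediationPosterior:
    """Apply the study's outcome orientation to the fitted effects.

    For lower-is-better outcomes every effect on the outcome (indirect,
    direct, total) is negated so that positive pooled estimates always mean
    better performance.  Implemented by negating the outcome-equation draws
    (alpha_y, beta3, beta4), which flips the derived indirect and total
    draws consistently; applying the operation twice restores the original.
    """
    orientation = Orientation(orientation)
    if orientation is Orientation.HIGHER_IS_BETTER:
        return posterior
    draws = dict(posterior.draws)
    for p in ("alpha_y", "beta3", "beta4"):
        draws[p] = -draws[p]
    return MediationPosterior(
        draws=draws,
        study_id=posterior.study_id,
        sign_flipped=not posterior.sign_flipped,
        converged=posterior.converged,
    )


def effect_estimate(
    posterior: MediationPosterior, quantity: str, outcome: str = ""
) -> EffectEstimate:
    """Reduce posterior draws of one effect to a meta-analysis-ready estimate."""
    if quantity == "indirect":
        d = posterior.indirect
    elif quantity == "direct":
        d = posterior.direct
    elif quantity == "total":
        d = posterior.total
    else:
        raise DomainError(f"unknown quantity {quantity!r}")
    s = summarize_effect(d)
    return EffectEstimate(
        study_id=posterior.study_id,
        quantity=quantity,
        y=s["mean"],
        v=float(np.var(d, ddof=1)),
        ci_low=s["q2.5"],
        ci_high=s["q97.5"],
        sign_flipped=posterior.sign_flipped,
        outcome=outcome,
    )
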