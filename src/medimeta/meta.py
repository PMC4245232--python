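"""Random-effects meta-analysis of standardised study effects.

Study-level posterior means y_i with posterior variances v_i are pooled
with inverse-variance weights w_i = 1/(v_i + tau^2), where tau^2 is the
between-study variance of the true effects.  tau^2 is estimated by the
empirical-Bayes / Paule-Mandel estimating equation

    sum_i w_i(tau^2) * (y_i - mu_hat(tau^2))^2 = k - 1,

solved by damped Newton iteration and truncated at zero; its standard
error uses the large-sample form sqrt(2 k^2 / (k - 1)) / sum_i w_i (the
same form metafor reports for this estimator).  Heterogeneity is tested
with Cochran's Q against a chi-square with k-1 degrees of freedom.
Pooled inference uses normal (z) intervals and p-values.

Because studies often contribute several outcomes or mediator markers,
only the most precise estimate (smallest v) per study enters the pooled
analysis, avoiding double counting of animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConvergenceError, DesignError, DomainError, EmptyInputError
from .mediation import EffectEstimate

__all__ = [
    "MetaResult",
    "select_most_precise",
    "eb_tau2",
    "q_statistic",
    "pool_random_effects",
    "random_effects_meta",
]

Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    tau2_se: float
    Q: float
    df: int
    p_Q: float
    k: int


def _extract(estimates: Sequence[EffectEstimate] | Iterable) -> tuple[np.ndarray, np.ndarray]:
    ests = list(estimates)
    if not ests:
        raise EmptyInputError("no effect estimates supplied")
    if isinstance(ests[0], EffectEstimate):
        y = np.array([e.y for e in ests], dtype=float)
        v = np.array([e.v for e in ests], dtype=float)
    else:  # (y, v) pairs
        arr = np.asarray(ests, dtype=float)
        y, v = arr[:, 0], arr[:, 1]
    if np.any(v <= 0):
        raise DomainError("all sampling variances must be positive")
    return y, v


def select_most_precise(
    estimates: Sequence[EffectEstimate],
    primary_outcome_order: Sequence[str] | None = None,
) -> list[EffectEstimate]:
    """Keep one estimate per study: the one with the smallest posterior variance.

    Ties are broken by the declared primary-outcome order if given, then by
    lexical outcome label, so the selection is deterministic.  Input order
    of studies is preserved.
    """
    ests = list(estimates)
    if not ests:
        raise EmptyInputError("no effect estimates supplied")
    order = {o: i for i, o in enumerate(primary_outcome_order or [])}

    def rank(e: EffectEstimate):
        return (e.v, order.get(e.outcome, len(order)), e.outcome)

    chosen: dict[str, EffectEstimate] = {}
    for e in ests:
        cur = chosen.get(e.study_id)
        if cur is None or rank(e) < rank(cur):
            chosen[e.study_id] = e
    return list(chosen.values())


def eb_tau2(
    estimates: Sequence[EffectEstimate],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Empirical-Bayes (Paule-Mandel) between-study variance and its SE.

    Iterates tau2 <- tau2 + (Q_gen(tau2) - (k-1)) / sum w_i^2 (y_i - mu_hat)^2,
    the Newton step for the generalised Q estimating equation, truncating
    negative iterates at zero.  Q_gen is decreasing in tau2, so if it is
    already below k-1 at tau2 = 0 the estimate is exactly 0.
    """
    y, v = _extract(estimates)
    k = len(y)
    if k < 2:
        raise DesignError("need >=2 estimates to estimate tau^2")

    def q_gen(t2: float) -> tuple[float, float]:
        w = 1.0 / (v + t2)
        mu = float(np.sum(w * y) / np.sum(w))
        resid2 = (y - mu) ** 2
        return float(np.sum(w * resid2)), float(np.sum(w**2 * resid2))

    tau2 = 0.0
    q0, _ = q_gen(0.0)
    if q0 <= k - 1:
        tau2 = 0.0
    else:
        # DerSimonian-Laird starting value
        w0 = 1.0 / v
        c = float(np.sum(w0) - np.sum(w0**2) / np.sum(w0))
        tau2 = max(q0 - (k - 1), 0.0) / c if c > 0 else 0.0
        converged = False
        for _ in range(max_iter):
            q, dq = q_gen(tau2)
            if dq == 0:
                break
            step = (q - (k - 1)) / dq
            new = max(tau2 + step, 0.0)
            if abs(new - tau2) < tol:
                tau2 = new
                converged = True
                break
            tau2 = new
        else:
            converged = False
        if not converged and abs(q_gen(tau2)[0] - (k - 1)) > 1e-6:
            raise ConvergenceError(
                f"Paule-Mandel iteration did not converge after {max_iter} "
                f"iterations; last iterate tau^2 = {tau2:.6g}",
                last_iterate=tau2,
            )

    w = 1.0 / (v + tau2)
    tau2_se = float(np.sqrt(2.0 * k**2 / (k - 1)) / np.sum(w))
    return float(tau2), tau2_se


def q_statistic(estimates: Sequence[EffectEstimate]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic, its df, and chi-square p-value."""
    y, v = _extract(estimates)
    k = len(y)
    if k < 2:
        raise DesignError("need >=2 estimates for a heterogeneity test")
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    df = k - 1
    p_Q = float(stats.chi2.sf(Q, df))
    return Q, df, p_Q


def pool_random_effects(
    estimates: Sequence[EffectEstimate], tau2: float, tau2_se: float = float("nan")
) -> MetaResult:
    """Inverse-variance pooled effect under the random-effects model.

    Weights are 1/(v_i + tau^2); the pooled standard error is
    sqrt(1 / sum w_i) and inference is normal-theory (z).
    """
    y, v = _extract(estimates)
    k = len(y)
    if k < 2:
        raise DesignError("need >=2 estimates to pool")
    if tau2 < 0:
        raise DomainError("tau^2 must be non-negative")
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    Q, df, p_Q = q_statistic(estimates)
    return MetaResult(
        pooled=pooled,
        se=se,
        ci_low=pooled - Z975 * se,
        ci_high=pooled + Z975 * se,
        p=p,
        tau2=float(tau2),
        tau2_se=float(tau2_se),
        Q=Q,
        df=df,
        p_Q=p_Q,
        k=k,
    )


def random_effects_meta(estimates: Sequence[EffectEstimate]) -> MetaResult:
    """Full random-effects meta-analysis: EB tau^2, Q test, pooled effect."""
    tau2, tau2_se = eb_tau2(estimates)
    return pool_random_effects(estimates, tau2, tau2_se)
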