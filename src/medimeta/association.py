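"""Within-group versus pooled mediator-outcome association.

If the causal hypothesis "more neurogenesis, better behaviour" is true at
the level of individual animals, it must show up *within* experimental
groups: among controls, and among treated animals, the ones with more new
neurons should perform better.  A regression through all animals that
ignores group structure conflates this individual-level association with
the group contrast, and can manufacture an association (or reverse its
sign) out of two clusters that are merely offset on both axes -- the
ecological fallacy.

The valid single-analysis test is the analysis of covariance: regress the
outcome on treatment plus mediator and read off the mediator slope, which
is the pooled within-group slope under a common-slope assumption.  This
module reports that slope next to the naive pooled slope and flags the
pattern where only the naive one is "significant".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .data_model import StandardizedStudy
from .errors import DegenerateDataError, DesignError

__all__ = ["AssociationResult", "EcologicalGapReport", "within_group_association", "ecological_gap"]

INTERACTION_ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    """Side-by-side within-group (ANCOVA) and pooled regression slopes."""

    study_id: str
    within_slope: float
    within_se: float
    within_p: float
    pooled_slope: float
    pooled_p: float
    interaction_p: float | None = None


@dataclass(frozen=True)
class EcologicalGapReport:
    """Diagnostic contrasting pooled and within-group association."""

    study_id: str
    pooled_slope: float
    pooled_p: float
    within_slope: float
    within_p: float
    flag: bool
    message: str


def within_group_association(
    study: StandardizedStudy, alpha: float = 0.05
) -> AssociationResult:
    """ANCOVA mediator slope (Y ~ T + M) and the naive pooled slope (Y ~ M).

    The within-group slope assumes a common slope across groups; a
    group x mediator interaction with p < 0.05 triggers a warning because a
    strong interaction means no single within-group slope exists.  With a
    single group the model reduces to a simple regression of Y on M.
    """
    T, M, Y = study.T, study.M, study.Y
    levels = np.unique(T)
    for t in levels:
        if len(M[T == t]) < 3:
            raise DesignError("need >=3 animals per group for the ANCOVA")
        if np.ptp(M[T == t]) == 0:
            raise DegenerateDataError(
                f"mediator is constant within group T={int(t)}; "
                "the within-group slope is undefined"
            )

    single_group = len(levels) == 1
    if single_group:
        X = sm.add_constant(M)
    else:
        X = np.column_stack([np.ones(len(T)), T, M])
    fit = sm.OLS(Y, X).fit()
    m_idx = X.shape[1] - 1
    within_slope = float(fit.params[m_idx])
    within_se = float(fit.bse[m_idx])
    within_p = float(fit.pvalues[m_idx])

    pooled_fit = sm.OLS(Y, sm.add_constant(M)).fit()
    pooled_slope = float(pooled_fit.params[1])
    pooled_p = float(pooled_fit.pvalues[1])

    interaction_p = None
    if not single_group:
        Xi = np.column_stack([np.ones(len(T)), T, M, T * M])
        if np.linalg.matrix_rank(Xi) == Xi.shape[1] and len(T) > Xi.shape[1]:
            fit_i = sm.OLS(Y, Xi).fit()
            interaction_p = float(fit_i.pvalues[3])
            if interaction_p < INTERACTION_ALPHA:
                warnings.warn(
                    f"study {study.meta.study_id!r}: group x mediator interaction "
                    f"p = {interaction_p:.3g}; a common within-group slope is "
                    "questionable",
                    stacklevel=2,
                )

    return AssociationResult(
        study_id=study.meta.study_id,
        within_slope=within_slope,
        within_se=within_se,
        within_p=within_p,
        pooled_slope=pooled_slope,
        pooled_p=pooled_p,
        interaction_p=interaction_p,
    )


def ecological_gap(result: AssociationResult, alpha: float = 0.05) -> EcologicalGapReport:
    """Flag a pooled association that evaporates once groups are respected.

    The flag is raised when the pooled slope is significant at ``alpha``
    while the within-group slope is not -- the tall-barbers-earn-more
    pattern, where the aggregate association is driven by between-group
    offsets rather than by individual-level covariation.
    """
    flag = result.pooled_p < alpha and result.within_p >= alpha
    if flag:
        message = (
            f"pooled slope {result.pooled_slope:.3f} (p={result.pooled_p:.3g}) is "
            f"significant but the within-group slope {result.within_slope:.3f} "
            f"(p={result.within_p:.3g}) is not: the aggregate association is "
            "driven by group offsets, not by individual-level covariation"
        )
    else:
        message = (
            f"pooled slope {result.pooled_slope:.3f} (p={result.pooled_p:.3g}); "
            f"within-group slope {result.within_slope:.3f} (p={result.within_p:.3g})"
        )
    return EcologicalGapReport(
        study_id=result.study_id,
        pooled_slope=result.pooled_slope,
        pooled_p=result.pooled_p,
        within_slope=result.within_slope,
        within_p=result.within_p,
        flag=flag,
        message=message,
    )
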