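"""Synthetic animal-study generator with the pipeline's assumed structure.

Studies are generated from the same graph the mediation model estimates:
a two-arm design in which treatment shifts the mediator, and the outcome
responds to both the mediator and the treatment directly,

    M = b1 * T + N(0, sigma_m),
    Y = b3 * M + b4 * T + N(0, sigma_y).

Values are produced on a raw (unstandardised) scale so that the
pipeline's own standardisation step is exercised, and for percent-bounded
outcomes Y is pushed through the inverse logit onto (0, 100).

Because the analysis reports effects in pooled standard-deviation units,
the raw coefficients (b1, b3, b4) map to *standardised* indirect and
direct effects through the population SD of Y; the helpers
:func:`standardized_effects_of` and :func:`spec_for_effects` convert in
both directions in closed form.  The default spec emulates the conditions
typical of the neurogenesis literature this pipeline was built for: 10
animals per arm, a strong treatment effect on the mediator (1.5 residual
SDs), and raw coefficients calibrated so the population standardised
indirect effect is 0.15 and the direct effect 1.06 with no between-study
heterogeneity -- a small mediated contribution riding on a large direct
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data_model import (
    AnimalRecord,
    Orientation,
    OutcomeScale,
    StudyDataset,
    StudyMeta,
    inverse_logit_percent,
)
from .errors import DomainError

__all__ = [
    "SyntheticStudySpec",
    "SyntheticEnsembleSpec",
    "generate_study",
    "generate_ensemble",
    "standardized_effects_of",
    "spec_for_effects",
]

CONTROL, TREATED = "control", "treated"


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Generative parameters for one simulated two-arm study.

    The default raw coefficients are the closed-form calibration of
    :func:`spec_for_effects` for standardised indirect 0.15 and direct
    1.06 with b1 = 1.5 and unit residual SDs.
    """

    n_control: int = 10
    n_treated: int = 10
    b1: float = 1.5
    b3: float = 0.12659495686752706
    b4: float = 1.341906542795787
    sigma_m: float = 1.0
    sigma_y: float = 1.0
    outcome_scale: OutcomeScale = OutcomeScale.LINEAR
    orientation: Orientation = Orientation.HIGHER_IS_BETTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_m <= 0 or self.sigma_y <= 0:
            raise DomainError("residual SDs must be positive")
        if min(self.n_control, self.n_treated) < 3:
            raise DomainError("need >=3 animals per arm")


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """A set of k studies whose true standardised indirect effects are drawn
    with variance ``tau2_between`` around the base spec's value (tau2 = 0
    means all studies share the base generative parameters)."""

    k: int = 11
    base: SyntheticStudySpec = SyntheticStudySpec()
    tau2_between: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise DomainError("an ensemble needs k >= 2 studies")
        if self.tau2_between < 0:
            raise DomainError("tau2_between must be non-negative")


def _treatment_fraction(spec: SyntheticStudySpec) -> float:
    return spec.n_treated / (spec.n_control + spec.n_treated)


def standardized_effects_of(spec: SyntheticStudySpec) -> tuple[float, float]:
    """Population standardised (indirect, direct) effects implied by a spec.

    With q = p(1-p) the variance of the arm indicator, the population SDs are
    sd(M)^2 = b1^2 q + sigma_m^2 and
    sd(Y)^2 = b3^2 sd(M)^2 + b4^2 q + 2 b1 b3 b4 q + sigma_y^2,
    and the standardised effects are b1*b3/sd(Y) and b4/sd(Y).
    """
    p = _treatment_fraction(spec)
    q = p * (1.0 - p)
    var_m = spec.b1**2 * q + spec.sigma_m**2
    var_y = (
        spec.b3**2 * var_m
        + spec.b4**2 * q
        + 2.0 * spec.b1 * spec.b3 * spec.b4 * q
        + spec.sigma_y**2
    )
    sd_y = math.sqrt(var_y)
    return spec.b1 * spec.b3 / sd_y, spec.b4 / sd_y


def spec_for_effects(
    indirect: float,
    direct: float,
    base: SyntheticStudySpec | None = None,
) -> SyntheticStudySpec:
    """Solve for raw (b3, b4) so the population standardised effects hit the
    targets, keeping b1 and the residual SDs of ``base``.

    Inverting :func:`standardized_effects_of` gives
    sd(Y)^2 = sigma_y^2 / (1 - I^2 var(M)/b1^2 - D^2 q - 2 I D q);
    the targets are infeasible when that denominator is not positive
    (the requested effects would exceed the total variance of Y).
    """
    base = base or SyntheticStudySpec()
    p = _treatment_fraction(base)
    q = p * (1.0 - p)
    var_m = base.b1**2 * q + base.sigma_m**2
    denom = 1.0 - indirect**2 * var_m / base.b1**2 - direct**2 * q - 2.0 * indirect * direct * q
    if denom <= 0:
        raise DomainError(
            f"standardised effects (indirect={indirect}, direct={direct}) are "
            "infeasible for the given b1 and residual SDs"
        )
    sd_y = math.sqrt(base.sigma_y**2 / denom)
    return replace(base, b3=indirect * sd_y / base.b1, b4=direct * sd_y)


def generate_study(
    spec: SyntheticStudySpec, study_id: str | None = None
) -> StudyDataset:
    """Generate one study dataset; identical spec and seed give identical data."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_control + spec.n_treated
    T = np.concatenate([np.zeros(spec.n_control), np.ones(spec.n_treated)])
    M = spec.b1 * T + rng.normal(0.0, spec.sigma_m, size=n)
    Y = spec.b3 * M + spec.b4 * T + rng.normal(0.0, spec.sigma_y, size=n)
    if spec.outcome_scale is OutcomeScale.PERCENT_BOUNDED:
        Y = inverse_logit_percent(Y)

    sid = study_id if study_id is not None else f"synthetic-{spec.seed}"
    meta = StudyMeta(
        study_id=sid,
        control_group=CONTROL,
        orientation=spec.orientation,
        outcome_scale=spec.outcome_scale,
        species_strain="synthetic",
        behaviour_test="synthetic-task",
        mediator_marker="synthetic-marker",
    )
    records = [
        AnimalRecord(
            animal_id=f"{sid}-a{i + 1}",
            group=CONTROL if t == 0 else TREATED,
            mediator=float(m),
            outcome=float(y),
        )
        for i, (t, m, y) in enumerate(zip(T, M, Y))
    ]
    return StudyDataset(meta=meta, records=records)


def generate_ensemble(spec: SyntheticEnsembleSpec) -> list[StudyDataset]:
    """Generate k studies with heterogeneity ``tau2_between`` in the true
    standardised indirect effect.

    Child seeds are derived deterministically as SeedSequence([ensemble
    seed, study index]), so one integer reproduces the whole ensemble.
    When tau2_between > 0, each study's raw coefficients are re-solved so
    its population standardised indirect effect equals the base value plus
    a N(0, tau2_between) deviation (the direct effect is held at the base
    value).
    """
    base_ind, base_dir = standardized_effects_of(spec.base)
    studies = []
    for i in range(spec.k):
        ss = np.random.SeedSequence([spec.seed, i])
        child_seed = int(ss.generate_state(1)[0] % (2**31))
        if spec.tau2_between > 0:
            delta = float(
                np.random.default_rng(np.random.SeedSequence([spec.seed, i, 1])).normal(
                    0.0, math.sqrt(spec.tau2_between)
                )
            )
            study_spec = spec_for_effects(base_ind + delta, base_dir, spec.base)
        else:
            study_spec = spec.base
        study_spec = replace(study_spec, seed=child_seed)
        studies.append(generate_study(study_spec, study_id=f"study-{i + 1:02d}"))
    return studies
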