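"""Study-level data structures and pre-fit transformations.

An animal study here is a two-group design in which an intervention
(exercise, irradiation, a transgene, ...) is applied to the treated arm and
two quantities are measured per animal: a *mediator* (a histological count
such as BrdU+, Ki67+ or DCX+ cells in the dentate gyrus) and a behavioural
*outcome* (escape latency, percent time freezing, immobility time, ...).

Before model fitting, mediator and outcome are standardised to z-scores
pooled across both groups, which puts studies with different assays and
tasks on a common standard-deviation scale without changing the group
contrast.  Outcomes bounded in (0, 100) percent are first mapped to the
logit scale so that a normal linear model is defensible.

Whether a *higher* or *lower* outcome value means better performance is
declared in :class:`StudyMeta`, never inferred from the data; the sign
convention is applied to fitted effects downstream, not to the raw data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    DesignError,
    DomainError,
    FormatError,
    ParseError,
    UnsupportedDesignError,
)

__all__ = [
    "Orientation",
    "OutcomeScale",
    "AnimalRecord",
    "StudyMeta",
    "StudyDataset",
    "StandardizedStudy",
    "read_study_csv",
    "standardize",
    "logit_transform_percent",
    "inverse_logit_percent",
    "prepare_study",
]

REQUIRED_COLUMNS = ("animal_id", "group", "mediator", "outcome")


class Orientation(str, enum.Enum):
    """Direction in which the raw outcome scale maps to performance."""

    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


class OutcomeScale(str, enum.Enum):
    """Measurement scale of the behavioural outcome."""

    LINEAR = "linear"
    PERCENT_BOUNDED = "percent_bounded"


@dataclass(frozen=True)
class AnimalRecord:
    """One animal: its group assignment, mediator and outcome measurements."""

    animal_id: str
    group: str
    mediator: float
    outcome: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mediator) and math.isfinite(self.outcome)):
            raise ParseError(
                f"animal {self.animal_id!r}: mediator/outcome must be finite, "
                f"got mediator={self.mediator}, outcome={self.outcome}"
            )


@dataclass(frozen=True)
class StudyMeta:
    """Declared study metadata.

    ``orientation`` and ``outcome_scale`` are part of the study's declared
    design; they are never guessed from the numbers.  ``control_group``
    names the group coded 0 in the treatment indicator.
    """

    study_id: str
    control_group: str
    orientation: Orientation = Orientation.HIGHER_IS_BETTER
    outcome_scale: OutcomeScale = OutcomeScale.LINEAR
    species_strain: str = ""
    behaviour_test: str = ""
    mediator_marker: str = ""

    def __post_init__(self) -> None:
        # tolerate plain strings from config files
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        object.__setattr__(self, "outcome_scale", OutcomeScale(self.outcome_scale))


@dataclass
class StudyDataset:
    """A study's metadata plus its animal-level records."""

    meta: StudyMeta
    records: list[AnimalRecord] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return list(seen)

    @property
    def n_animals(self) -> int:
        return len(self.records)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self.records:
            sizes[r.group] = sizes.get(r.group, 0) + 1
        return sizes

    def validate(self) -> None:
        """Check the design invariants: >=2 groups, >=3 animals/group,
        a non-constant mediator, and a control label that matches a group."""
        groups = self.groups
        if len(groups) < 2:
            raise DesignError(
                f"study {self.meta.study_id!r}: needs >=2 groups, found {groups}"
            )
        if self.meta.control_group not in groups:
            raise DesignError(
                f"study {self.meta.study_id!r}: control group "
                f"{self.meta.control_group!r} not among groups {groups}"
            )
        for g, n in self.group_sizes().items():
            if n < 3:
                raise DesignError(
                    f"study {self.meta.study_id!r}: group {g!r} has {n} animals, "
                    "need >=3"
                )
        med = np.array([r.mediator for r in self.records])
        if np.ptp(med) == 0:
            raise DegenerateDataError(
                f"study {self.meta.study_id!r}: mediator is constant"
            )


@dataclass
class StandardizedStudy:
    """Model-ready arrays for one two-group study.

    T is the 0/1 treatment indicator (control = 0); M and Y are the
    mediator and outcome as pooled z-scores.  ``meta`` is carried along so
    the outcome orientation can be applied to fitted effects later.
    """

    T: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    meta: StudyMeta

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if not (len(self.T) == len(self.M) == len(self.Y)):
            raise DesignError("T, M, Y must have equal length")

    @property
    def n(self) -> int:
        return len(self.T)


def read_study_csv(path, meta: StudyMeta) -> StudyDataset:
    """Read one study's animal-level table from CSV.

    The file must have a header row with columns ``animal_id``, ``group``,
    ``mediator`` and ``outcome`` (UTF-8, "." decimal point).  Row order is
    preserved.  Rows whose mediator or outcome does not parse as a number
    raise :class:`ParseError` naming the offending row (1-based, counting
    data rows).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: could not read CSV: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = {}
        for col in ("mediator", "outcome"):
            raw = getattr(row, col)
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: row {i}: non-numeric {col} value {raw!r}"
                ) from None
            if not math.isfinite(vals[col]):
                raise ParseError(f"{path}: row {i}: non-finite {col} value {raw!r}")
        records.append(
            AnimalRecord(
                animal_id=str(row.animal_id),
                group=str(row.group),
                mediator=vals["mediator"],
                outcome=vals["outcome"],
            )
        )

    ds = StudyDataset(meta=meta, records=records)
    if len(ds.groups) < 2:
        raise DesignError(
            f"{path}: study must have >=2 groups, found {ds.groups}"
        )
    return ds


def standardize(values) -> np.ndarray:
    """Return z-scores: mean 0, sample standard deviation 1 (n-1 denominator).

    Raises :class:`DegenerateDataError` for constant input and
    :class:`DesignError` for fewer than two values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise DesignError(f"standardize needs >=2 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("cannot standardize constant values")
    return (x - x.mean()) / sd


def logit_transform_percent(values, clamp: bool = False, eps: float = 0.005):
    """Map percentages in (0, 100) to the logit scale, log(p/(1-p)) with p=v/100.

    Values of exactly 0 or 100 are outside the domain; by default they raise
    :class:`DomainError`.  With ``clamp=True`` the proportion is clamped to
    [eps, 1-eps] first (a deliberate, visible choice -- silent clamping can
    bias estimates).
    """
    x = np.asarray(values, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    p = x / 100.0
    if clamp:
        p = np.clip(p, eps, 1.0 - eps)
    elif np.any((p <= 0.0) | (p >= 1.0)):
        bad = x[(p <= 0.0) | (p >= 1.0)]
        raise DomainError(
            f"percent values must lie strictly in (0, 100); got {bad.tolist()} "
            "(pass clamp=True to clamp to the open interval)"
        )
    out = np.log(p / (1.0 - p))
    return float(out[0]) if scalar else out


def inverse_logit_percent(values):
    """Inverse of :func:`logit_transform_percent`: 100 * e^x / (1 + e^x)."""
    x = np.asarray(values, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    # numerically stable logistic
    out = 100.0 * np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                           np.exp(x) / (1.0 + np.exp(x)))
    return float(out[0]) if scalar else out


def prepare_study(
    dataset: StudyDataset, *, clamp_percent: bool = False, eps: float = 0.005
) -> StandardizedStudy:
    """Turn a validated two-group dataset into model-ready standardised arrays.

    Percent-bounded outcomes are logit-transformed before standardisation.
    Standardisation is pooled across both groups (per-group z-scoring would
    erase the very group effect the model estimates).  Orientation metadata
    is carried forward; the sign convention is applied to fitted effects,
    not here.
    """
    dataset.validate()
    groups = dataset.groups
    if len(groups) > 2:
        raise UnsupportedDesignError(
            f"study {dataset.meta.study_id!r} has {len(groups)} groups "
            f"({groups}); only two-group designs are supported -- split the "
            "study into control-vs-arm contrasts upstream if appropriate"
        )

    T = np.array(
        [0.0 if r.group == dataset.meta.control_group else 1.0 for r in dataset.records]
    )
    mediator = np.array([r.mediator for r in dataset.records])
    outcome = np.array([r.outcome for r in dataset.records])
    if dataset.meta.outcome_scale is OutcomeScale.PERCENT_BOUNDED:
        outcome = logit_transform_percent(outcome, clamp=clamp_percent, eps=eps)

    return StandardizedStudy(
        T=T, M=standardize(mediator), Y=standardize(outcome), meta=dataset.meta
    )
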