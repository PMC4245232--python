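"""Exception hierarchy for medimeta.

All package errors derive from :class:`MediMetaError` so callers can catch
one base class; subclasses distinguish contract violations (bad files, bad
designs) from numerical failures (degenerate data, non-convergence).
"""


class MediMetaError(Exception):
    """Base class for all medimeta errors."""


class FormatError(MediMetaError):
    """An input file does not have the required structure (e.g. missing column)."""


class ParseError(MediMetaError):
    """A value in an input file could not be parsed; the message names the row."""


class DesignError(MediMetaError):
    """The study design violates a precondition (too few groups, too few animals)."""


class UnsupportedDesignError(DesignError):
    """A valid but unsupported design, e.g. more than two groups."""


class DegenerateDataError(MediMetaError):
    """Data with no usable variation (constant mediator, zero variance)."""


class DomainError(MediMetaError):
    """A value lies outside the mathematical domain of a transform."""


class PrecisionError(MediMetaError):
    """Too few posterior draws to summarise at the requested precision."""

class ConvergenceError(MediMetaError):
    """An iterative estimator failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class ConsistencyError(MediMetaError):
    """Internal invariant violated (e.g. misaligned posterior draw vectors)."""


class EmptyInputError(MediMetaError):
    """An operation received no usable input."""
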