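"""Exception hierarchy for the assay pipeline.

Each class maps to a distinct CLI exit code (see :mod:`atflow.cli`), so shell
pipelines can distinguish a dry chip from a bad config from a corrupt file.
"""


class AssayError(Exception):
    """Base class for all atflow errors."""

    exit_code = 1


class InvalidInputError(AssayError, ValueError):
    """A value violates an operation's precondition (negative concentration, ...)."""

    exit_code = 1


class ConfigurationError(AssayError):
    """Geometry/threshold/unit configuration is out of range or inconsistent."""

    exit_code = 2


class NoFlowError(AssayError):
    """No flow onset could be detected in the profile (dry chip, idle-only video)."""

    exit_code = 3


class QualityFailureError(AssayError):
    """Too few usable frames on a measurement line to trust the estimate."""

    exit_code = 4


class AssayIOError(AssayError, IOError):
    """An input file is missing or unreadable; the message names the file."""

    exit_code = 5


class InsufficientDataError(InvalidInputError):
    """Fewer data points than the operation mathematically requires."""


class DegenerateCurveError(InvalidInputError):
    """A standard curve with zero slope cannot be inverted."""


class GenerationError(AssayError):
    """The synthetic generator could not satisfy its constraints (e.g. object placement)."""


class UndefinedFError(InvalidInputError):
    """ANOVA F statistic is 0/0: no variance within or between groups."""
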