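"""Exception hierarchy.

Errors are grouped so the CLI can map them onto exit codes:
usage/configuration problems, data problems, and numerical failures.
"""


class AccelmixError(Exception):
    """Base class for all package errors."""


class ConfigError(AccelmixError):
    """Invalid configuration value or unknown feature/field name."""


class InputError(AccelmixError):
    """Malformed or empty input file."""


class ParseError(InputError):
    """Non-numeric or otherwise unparseable row; names the offending line."""


class SamplingError(InputError):
    """Irregular timestamps or a rate mismatch between file and user."""


class InputTooShortError(InputError):
    """Series shorter than a filter warm-up or smoothing window."""


class ConsistencyError(AccelmixError):
    """Internally inconsistent objects (e.g. intervals not tiling a series)."""


class InsufficientDataError(AccelmixError):
    """Too few samples for a statistical operation."""


class NumericalError(AccelmixError):
    """Base for numerical failures."""


class DegenerateFitError(NumericalError):
    """All EM initializations collapsed onto a singular component."""


class DegenerateFeatureError(NumericalError):
    """A feature column is constant and cannot be standardized."""


class DegenerateDesignError(NumericalError):
    """Singular pooled covariance in the discriminant fit."""
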