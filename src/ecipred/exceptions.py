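"""Exception hierarchy shared across the package.

All package errors derive from :class:`EciError` so callers can catch the
library's failures without masking programming errors.
"""


class EciError(Exception):
    """Base class for all errors raised by this package."""


class DatasetLoadError(EciError):
    """A dataset file is missing or unreadable."""


class ConsistencyError(EciError):
    """Cross-file identifiers disagree (e.g. activity header vs chemicals)."""


class ValidationError(EciError):
    """A dataset or configuration violates a structural invariant."""


class DomainError(EciError):
    """An input value is outside the operation's mathematical domain."""


class UndefinedStatisticError(EciError):
    """A dataset statistic is undefined for the given input (e.g. one enzyme)."""


class UndefinedMetricError(EciError):
    """A performance metric is undefined (e.g. single-class labels).

    During cross-validation this is caught and the fold is skipped and
    logged rather than silently imputed.
    """


class DegenerateTrainingError(EciError):
    """The training set cannot support fitting (e.g. a single class)."""


class ConfigurationError(EciError):
    """A run configuration is invalid (e.g. more folds than objects)."""


class LookupError_(EciError):
    """An object id is missing from a descriptor table."""


class CapacityError(EciError):
    """A generator was asked for more objects than it can supply."""
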