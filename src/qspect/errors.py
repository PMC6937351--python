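"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`ArgumentError` family -> 2, :class:`DataError`
family -> 3 (see :mod:`qspect.cli`).
"""


class QSpectError(Exception):
    """Base class for all package errors."""


class ArgumentError(QSpectError, ValueError):
    """A caller supplied an invalid parameter value."""


class DataError(QSpectError):
    """Input data violate a contract (negative counts, empty sample, ...)."""


class GeometryError(DataError):
    """A geometric precondition failed (overlapping inserts, empty VOI, ...)."""


class ConfigurationError(QSpectError):
    """Mismatched or inconsistent configuration (e.g. wrong scanner profile)."""


class CountRateWarning(UserWarning):
    """Camera count rate above the recommended calibration limit."""


class ContrastRecoveryWarning(UserWarning):
    """A contrast recovery coefficient outside the physically expected [0, 1]."""
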