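"""Exception hierarchy shared across the package."""


class SpatHealthError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(SpatHealthError, ValueError):
    """A generator or model specification violates its constraints."""


class InvalidScheduleError(SpatHealthError, ValueError):
    """An age schedule violates life-table invariants."""


class DegenerateTerminalError(SpatHealthError, ValueError):
    """Terminal interval has zero mortality but surviving population."""


class ZeroVarianceError(SpatHealthError, ValueError):
    """A statistic is undefined because the input has no variance."""


class UndefinedGiniError(SpatHealthError, ValueError):
    """Gini coefficient undefined (e.g. all resources zero)."""


class InvalidTableError(SpatHealthError, ValueError):
    """Allocation table violates its invariants."""


class SingularDesignError(SpatHealthError, ValueError):
    """Regression design matrix is rank deficient."""


class DimensionError(SpatHealthError, ValueError):
    """Array shapes are inconsistent."""


class InsufficientDataError(SpatHealthError, ValueError):
    """Too few observations for the requested fit."""


class EmptyCurveError(SpatHealthError, ValueError):
    """No units survive the significance filter for a ratio curve."""


class IntegrityError(SpatHealthError, ValueError):
    """A data file violates panel integrity constraints."""
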