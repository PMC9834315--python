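"""Error taxonomy shared across the pipeline.

All exceptions derive from :class:`CfsDecodeError` so callers can catch the
package's failures with one clause; each subclass marks which contract was
violated (configuration vs data vs model state).
"""


class CfsDecodeError(Exception):
    """Base class for all cfsdecode errors."""


class ConfigurationError(CfsDecodeError, ValueError):
    """A structural parameter is inconsistent (grid/image shape, fold counts...)."""


class DomainError(CfsDecodeError, ValueError):
    """A value lies outside its mathematical domain (negative energy, n < 1...)."""


class DataError(CfsDecodeError, ValueError):
    """Supplied data violate a precondition (missing features, unset responses...)."""


class DegenerateModelError(CfsDecodeError, RuntimeError):
    """No usable features remain for a classifier fit."""


class DegenerateTestError(CfsDecodeError, RuntimeError):
    """A statistical test has no information left (e.g. all paired differences zero)."""


class UndefinedCorrelationError(CfsDecodeError, RuntimeError):
    """A correlation is undefined because a retained vector has zero variance."""


class StateError(CfsDecodeError, RuntimeError):
    """An operation was called on an object in an invalid state (empty pools...)."""
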