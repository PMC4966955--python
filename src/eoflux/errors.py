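"""Exception hierarchy.

All eoflux errors derive from :class:`EofluxError` so callers can catch the
package's failures without swallowing unrelated bugs.
"""


class EofluxError(Exception):
    """Base class for all errors raised by eoflux."""


class FormatError(EofluxError, ValueError):
    """A file does not have the expected structure (missing variable/column)."""


class ValidationError(EofluxError, ValueError):
    """Input data violates a documented precondition or invariant."""


class ParameterError(EofluxError, ValueError):
    """A caller-supplied parameter is outside its documented range."""


class NumericError(EofluxError, ValueError):
    """Non-finite values where finite numbers are required."""


class ContractError(EofluxError, RuntimeError):
    """A user-supplied callback violated its contract (e.g. wrong tile shape)."""


class InsufficientDataError(EofluxError, ValueError):
    """Too few valid observations to compute the requested statistic."""


class UndefinedCorrectionError(EofluxError, ZeroDivisionError):
    """Energy-balance closure correction is undefined (H_ori + LE_ori == 0)."""
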