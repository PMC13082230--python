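"""Exception hierarchy.

All library errors derive from :class:`SipRamanError` so callers can catch
one base class; subclasses distinguish bad files from bad numbers from bad
parameters, which matters for CLI exit codes.
"""


class SipRamanError(Exception):
    """Base class for all errors raised by sipraman."""


class FormatError(SipRamanError):
    """A file does not follow the expected text format (missing columns, bad JSON)."""


class ValidationError(SipRamanError):
    """Data violates a domain invariant (non-finite values, unsorted axis, duplicate ids)."""


class RangeError(SipRamanError):
    """A requested wavenumber range falls outside the available axis."""


class ParameterError(SipRamanError):
    """An operation was called with invalid parameters (empty set, bad window)."""


class AxisError(SipRamanError):
    """Spectra that must share a wavenumber axis do not."""


class NormalizationError(SipRamanError):
    """Normalization was requested on a spectrum with no signal."""


class LookupError_(SipRamanError):
    """An identifier does not name a packaged resource."""


class ConfigurationError(SipRamanError):
    """A profile/table combination cannot support the requested operation."""


class UndefinedInputError(SipRamanError):
    """A derived quantity was requested from a failed upstream result."""
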