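"""Exception hierarchy shared across the package.

All errors derive from :class:`OmrexError` so callers can catch one base
class; the subclasses map onto the distinct failure modes of the analysis
(invalid measurements, configuration problems, degenerate statistical
designs, and data that cannot support the requested estimate).
"""


class OmrexError(Exception):
    """Base class for all omrex errors."""


class InvalidMeasurementError(OmrexError, ValueError):
    """A physical measurement violates its constraints (e.g. non-positive
    cell dimensions, reversed max/min, negative abundance)."""


class ConfigurationError(OmrexError, ValueError):
    """A configuration table is inconsistent or incomplete (missing carbon
    counts, zero filter retention, endmember mismatch, ...)."""


class InsufficientDataError(OmrexError, ValueError):
    """Too few observations for the requested fit or test."""


class DegenerateDesignError(OmrexError, ValueError):
    """The design matrix or variance structure is degenerate (zero time
    variance, zero combined diversity variance, constant covariate)."""


class NoGrowthError(OmrexError, ValueError):
    """An abundance series never shows a significant net-growth interval,
    so no stationary phase can be defined."""


class ImplausibleBiomassError(OmrexError, ValueError):
    """Bacterial biomass meets or exceeds the bulk organic carbon it is
    being subtracted from."""


class UndefinedBGEError(OmrexError, ValueError):
    """Growth efficiency requested from non-positive rates."""
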