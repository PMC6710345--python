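"""Exception hierarchy.

Two error families are distinguished because the command line maps them to
different exit codes: problems with user-supplied data (:class:`ValidationError`)
and problems with the configuration of the run itself
(:class:`ConfigurationError`).
"""


class SoilRiskNetError(Exception):
    """Base class for all package errors."""


class ValidationError(SoilRiskNetError):
    """Input data violates a documented precondition (e.g. negative
    concentration, missing 16S counts, empty group)."""


class ConfigurationError(SoilRiskNetError):
    """The run configuration is inconsistent (e.g. a metal without a
    reference entry, an unknown export format, a non-positive-definite
    correlation target)."""
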