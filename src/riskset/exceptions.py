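"""Exception hierarchy.

``ValidationError`` signals a malformed scenario or configuration;
``DomainError`` signals a mathematically undefined request on valid
inputs (zero cells, extinct cohorts, unstable step sizes).  Both derive
from ``ValueError`` so callers may catch broadly.
"""


class RisksetError(ValueError):
    """Base class for all errors raised by this package."""


class ValidationError(RisksetError):
    """A scenario, configuration or count failed validation."""


class DomainError(RisksetError):
    """An operation is undefined for these (otherwise valid) inputs."""


class UnsupportedDesignError(DomainError):
    """A sampling design was requested outside its domain of validity."""
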