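"""Exception hierarchy.

All burdenkit errors derive from :class:`BurdenKitError` so callers can catch
one type at the pipeline boundary.
"""


class BurdenKitError(Exception):
    """Base class for all burdenkit errors."""


class ConfigurationError(BurdenKitError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(BurdenKitError):
    """A file does not conform to the declared dialect or schema."""


class IntegrityError(BurdenKitError):
    """Data violates an internal invariant (e.g. AC > AN)."""


class DomainError(BurdenKitError):
    """A numeric argument lies outside the mathematical domain of a formula."""


class UndefinedFrequencyError(DomainError):
    """Allele frequency requested where AN == 0 (distinct from AF = 0)."""


class DispatchError(BurdenKitError):
    """No genetic-prevalence rule exists for the requested inheritance mode."""
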