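"""Exception hierarchy for pipeline validation and analysis failures."""


class CloverwatchError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CloverwatchError):
    """A table is missing a required column or has an unusable dtype."""


class ReferentialError(CloverwatchError):
    """A record refers to an entity (frame, inflorescence) that does not exist."""


class DomainValueError(CloverwatchError, ValueError):
    """A field value lies outside its documented domain."""


class DegenerateDataError(CloverwatchError):
    """The data cannot support the requested statistic (empty group, zero
    margin, zero variance, all-zero weights, or too few observations)."""


class ConfigurationError(CloverwatchError):
    """An option or simulation configuration value is invalid."""
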