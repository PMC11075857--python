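"""Exception hierarchy shared across the package."""


class UpliftRulesError(Exception):
    """Base class for package errors."""


class SchemaError(UpliftRulesError):
    """A column, feature or level is missing from or inconsistent with the schema."""


class ValidationError(UpliftRulesError):
    """Data values violate a contract (encodings, ranges, missingness)."""


class ConfigError(UpliftRulesError):
    """A configuration value is out of its allowed domain."""
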