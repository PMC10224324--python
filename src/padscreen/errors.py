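"""Exception types raised across the package."""


class PadScreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PadScreenError):
    """A cohort table or config file does not match its documented schema."""


class DataError(PadScreenError):
    """A row-level data problem: bad date, orphan event, invalid value."""


class RuleSetError(PadScreenError):
    """An invalid or inconsistent rule-set configuration."""
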