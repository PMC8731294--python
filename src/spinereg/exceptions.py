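"""Exception hierarchy shared across the toolkit."""


class SpineRegError(Exception):
    """Base class for all spinereg errors."""


class FormatError(SpineRegError, ValueError):
    """A file exists but cannot be parsed as the expected format."""


class ConfigError(SpineRegError, ValueError):
    """A configuration object violates its invariants."""


class DomainError(SpineRegError, ValueError):
    """A physical point lies outside the domain a transform covers."""
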