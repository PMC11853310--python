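"""Exception types shared across the toolkit."""


class PermodError(Exception):
    """Base class for all permod errors."""


class FormatError(PermodError):
    """A file does not conform to the expected format (missing columns, bad header)."""


class ValidationError(PermodError):
    """A value violates a domain invariant (e.g. probability outside [0, 1])."""


class TagConsistencyError(PermodError):
    """MM/ML modification tags of an alignment are mutually inconsistent."""


class ConsistencyError(PermodError):
    """Inputs that must agree (e.g. calls vs. template alignments) do not."""


class ConfigError(PermodError):
    """A generator or pipeline configuration is invalid or unattainable."""
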