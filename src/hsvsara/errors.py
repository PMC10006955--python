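"""Exception types shared across the package."""


class ContractViolation(ValueError):
    """An input violates a documented precondition (shape, range, tag, ...)."""


class ConfigError(ValueError):
    """A run configuration is malformed or internally inconsistent."""


class ArchiveError(IOError):
    """A compressed-image archive is corrupt, truncated, or version-incompatible."""
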