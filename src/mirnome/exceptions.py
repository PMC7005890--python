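"""Exception hierarchy shared across the package."""


class MirnomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirnomeError):
    """A file does not follow the expected dialect (e.g. RCC missing a section)."""


class IntegrityError(MirnomeError):
    """Cross-references between inputs do not line up (duplicate ids,
    sample present in the table but absent from the sheet, missing factors)."""


class ConfigurationError(MirnomeError):
    """An operation was asked to run with an impossible configuration
    (no negative-control probes, an empty reference set, an empty group)."""


class DegenerateInputError(MirnomeError):
    """Input is structurally valid but too small for the operation
    (fewer than two pooled negative counts, fewer than two probes)."""
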