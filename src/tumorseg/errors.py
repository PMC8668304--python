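"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`TumorsegError` so callers (and the
CLI) can map failures to exit codes without string matching.
"""


class TumorsegError(Exception):
    """Base class for all package errors."""


class ConfigError(TumorsegError):
    """Invalid configuration value or malformed config file."""


class FormatError(TumorsegError):
    """Unsupported or malformed image/mask format."""


class SizeError(TumorsegError):
    """Image dimensions incompatible with an operation."""


class DegenerateInputError(TumorsegError):
    """Input is formally valid but degenerate (constant image, empty batch)."""


class PlacementError(TumorsegError):
    """A phantom tumor cannot be placed inside the brain region."""


class StrippingError(TumorsegError):
    """Skull stripping found no usable foreground."""


class DependencyError(TumorsegError):
    """A pipeline stage was skipped but a later stage needs its artifact."""
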