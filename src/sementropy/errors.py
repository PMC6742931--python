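"""Exception types shared across the package."""


class SementropyError(Exception):
    """Base class for all package-specific errors."""


class EmptyGraphError(SementropyError):
    """Raised when an operation requires a non-empty graph."""


class NoPathsError(SementropyError):
    """Raised when no walk of the requested length exists."""


class InstanceTooLargeError(SementropyError):
    """Raised when exact walk enumeration would exceed the walk-count cap."""


class NoTaggedVoxelsError(SementropyError):
    """Raised when a volume contains only background."""


class NonErgodicError(SementropyError):
    """Raised when a transition model has no unique stationary distribution."""
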