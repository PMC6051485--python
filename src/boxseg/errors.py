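"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A network spec or config violates one of its structural rules."""


class InputError(ValueError):
    """An input array, box or scribble set fails a precondition."""


class StateError(RuntimeError):
    """An operation was called in an inconsistent state (e.g. stale cache)."""
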