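"""Exception types shared across the pipeline."""


class RotorkitError(Exception):
    """Base class for all rotorkit errors."""


class ConfigurationError(RotorkitError):
    """A tissue/solver configuration violates an invariant (e.g. stability)."""


class ProtocolError(RotorkitError):
    """A stimulation protocol is inconsistent with the tissue geometry."""


class InputError(RotorkitError):
    """An input array or file does not satisfy the operation's preconditions."""


class FitError(RotorkitError):
    """A regression or geometric fit is degenerate."""
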