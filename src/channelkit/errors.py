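"""Exception hierarchy shared across the package."""


class ChannelKitError(Exception):
    """Base class for all package errors."""


class ValidationError(ChannelKitError, ValueError):
    """An input violates a documented precondition."""


class ProtocolError(ChannelKitError):
    """The application protocol lacks an epoch a stage requires."""


class DegenerateSchemeError(ChannelKitError):
    """The kinetic scheme has no well-defined stationary distribution."""


class NoResponseError(ChannelKitError):
    """Trace amplitude is below the non-responder floor."""


class FitError(ChannelKitError):
    """A least-squares fit cannot be performed on the given data."""
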