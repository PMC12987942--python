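"""Exception hierarchy shared across the package."""


class MicrospikeError(ValueError):
    """Base class for all domain errors raised by microspike."""


class ValidationError(MicrospikeError):
    """An object violates one of its declared invariants."""


class FormatError(MicrospikeError):
    """A container file is malformed; the message names the missing piece."""


class EmptyInputError(MicrospikeError):
    """An operation received an empty collection it cannot work with."""


class InsufficientDataError(MicrospikeError):
    """Too few observations for the requested computation."""


class BoundaryError(MicrospikeError):
    """A waveform window would be clipped by the recording edge."""


class DegenerateSignalError(MicrospikeError):
    """The signal segment carries no usable structure (flat trace, zero MAD)."""
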