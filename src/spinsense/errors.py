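"""Exception types shared across the package."""


class InvalidArgument(ValueError):
    """An argument violates a documented precondition."""


class ChamberOverflowError(RuntimeError):
    """A simulated liquid transfer would exceed the target chamber capacity."""

    def __init__(self, chamber_id: str, volume: float, capacity: float):
        self.chamber_id = chamber_id
        self.volume = volume
        self.capacity = capacity
        super().__init__(
            f"transfer into chamber {chamber_id!r} would hold {volume:.1f} uL, "
            f"exceeding its capacity of {capacity:.1f} uL"
        )


class DegenerateHistogramError(ValueError):
    """The masked intensity histogram has a single value; no threshold exists."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending row/field."""
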