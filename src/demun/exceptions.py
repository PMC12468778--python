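"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An operator, projector, loss or experiment configuration is invalid."""


class ShapeError(ValueError):
    """An array does not have the shape an operation requires."""

    def __init__(self, what: str, expected, actual):
        super().__init__(f"{what}: expected shape {expected}, got {actual}")
        self.expected = expected
        self.actual = actual


class UndefinedSNRError(ValueError):
    """Input SNR is requested for a noiseless (sigma = 0) model."""
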