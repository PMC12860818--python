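"""Exception hierarchy for fractalperf."""


class FractalPerfError(Exception):
    """Base class for all fractalperf errors."""


class InvalidInputError(FractalPerfError, ValueError):
    """An input violates a precondition (shape, range, monotonicity ...)."""


class DegenerateInputError(FractalPerfError, ValueError):
    """Input is formally valid but degenerate (e.g. zero-variance baseline)."""


class UnitError(FractalPerfError, ValueError):
    """An operation was applied to a volume in the wrong intensity unit."""


class FormatError(FractalPerfError, IOError):
    """A file could not be read as the expected volumetric format."""
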