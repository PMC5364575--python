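"""Exception hierarchy for segquant."""


class SegquantError(Exception):
    """Base class for all segquant errors."""


class DimensionError(SegquantError):
    """Input array has an incompatible shape or is too small."""


class DegenerateInputError(SegquantError):
    """Input is degenerate (all-zero image, empty mask, ...)."""


class ParameterError(SegquantError):
    """A method parameter is outside its documented range."""


class ThresholdSelectionError(SegquantError):
    """No admissible valley/threshold could be found.

    Carries the diagnostics needed to understand the failure (detected
    peaks and valleys) in ``args[1]`` when available.
    """


class CalibrationError(SegquantError):
    """Calibration could not reach the requested number of peaks."""
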