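"""Exception hierarchy for the fractalperf pipeline."""


class FractalPerfError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(FractalPerfError, ValueError):
    """A parameter is outside its admissible range."""


class InputError(FractalPerfError, ValueError):
    """An input object violates a precondition (empty mask, non-finite data, ...)."""


class CalibrationError(FractalPerfError, RuntimeError):
    """Intensity calibration is degenerate or was applied twice."""


class DegenerateTextureError(FractalPerfError, RuntimeError):
    """Blanket surface area is non-positive at a requested scale."""


class EmptyCoreError(FractalPerfError, RuntimeError):
    """Core segmentation produced no enhancing component at the seed."""


class EmptyBandError(FractalPerfError, RuntimeError):
    """Margin band is empty (e.g. the whole core boundary touches the capsule)."""


class UndefinedStatisticError(FractalPerfError, RuntimeError):
    """A statistic is undefined for the given inputs (zero denominator, single class)."""
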