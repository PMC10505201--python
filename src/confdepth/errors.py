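"""Exception hierarchy for confdepth.

Every error raised deliberately by the package derives from
:class:`ConfdepthError`, so callers can catch the whole family while still
discriminating on the specific failure mode.
"""

from __future__ import annotations


class ConfdepthError(Exception):
    """Base class for all confdepth errors."""


class FormatError(ConfdepthError):
    """A file's on-disk structure is malformed (bad header, truncated data)."""


class UnsupportedFormatError(FormatError):
    """The file is recognisable but in a variant we do not handle
    (colour PFM, 8-bit or multi-channel PNG)."""


class DimensionError(ConfdepthError):
    """Shapes of paired maps disagree."""


class DomainError(ConfdepthError):
    """A scalar argument is outside its mathematical domain
    (confidence outside [0,1], threshold t <= 1, non-positive depth)."""


class InsufficientDataError(ConfdepthError):
    """Too few valid pixels to solve the requested problem."""


class DegenerateInputError(ConfdepthError):
    """The 2x2 normal equations are singular (constant prediction).

    Carries the shift-only fallback ``t = mean(gt) - mean(pred)`` so a
    caller that can live without a scale still gets something useful.
    """

    def __init__(self, message: str, fallback_shift: float | None = None):
        super().__init__(message)
        self.fallback_shift = fallback_shift


class RobustDegeneracyError(ConfdepthError):
    """IRLS downweighted every observation to zero.

    ``iteration`` records the sweep at which the weights collapsed.
    """

    def __init__(self, message: str, iteration: int):
        super().__init__(message)
        self.iteration = iteration


class EmptyImageError(ConfdepthError):
    """An operation that averages over valid pixels received none."""


class EmptyBatchError(ConfdepthError):
    """A batch-level operation received empty lists."""


class EvaluationError(ConfdepthError):
    """A metrics evaluation could not be carried out for an image."""


class ConfigError(ConfdepthError):
    """A configuration is internally inconsistent (e.g. corruption blobs
    covering the whole image)."""


class DivergenceError(ConfdepthError):
    """The trainer hit a non-finite loss.

    ``step`` and ``step_size`` identify where the optimisation blew up.
    """

    def __init__(self, message: str, step: int, step_size: float):
        super().__init__(message)
        self.step = step
        self.step_size = step_size
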