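"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration/schema problems -> 2,
analysis failures -> 3.
"""


class CapnetError(Exception):
    """Base class for all package errors."""


class InputError(CapnetError):
    """Malformed or inconsistent user input (bad ids, empty masks, ...)."""


class SchemaError(InputError):
    """A required column or sheet is missing from an input table."""


class ParseError(InputError):
    """A cell could not be parsed as the expected type."""


class StructureError(InputError):
    """A junction row violates the 3-segment vascular junction structure."""


class ConfigurationError(CapnetError):
    """Invalid generator or pipeline configuration."""


class GenerationError(CapnetError):
    """A synthetic-data generator could not honour its contract."""


class AnalysisError(CapnetError):
    """An analysis is undefined for the given network/data (no feeder, ...)."""


class InsufficientDataError(AnalysisError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(AnalysisError):
    """Pearson correlation undefined (constant input)."""


class UndefinedPulsatilityError(AnalysisError):
    """Pulsatility denominator v_max + v_min is zero."""


class AmbiguousPeakError(AnalysisError):
    """Depth profile has no unique-peak structure (all slabs equal)."""


class ThresholdError(AnalysisError):
    """Automatic thresholding failed (constant image)."""
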