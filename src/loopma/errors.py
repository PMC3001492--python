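"""Exception hierarchy for the loopma pipeline."""


class LoopmaError(Exception):
    """Base class for all loopma errors."""


class DesignError(LoopmaError):
    """Invalid or inconsistent hybridization design."""


class FormatError(LoopmaError):
    """Malformed input table (missing column, duplicate probe, ...)."""


class NormalizationError(LoopmaError):
    """Normalization cannot proceed (too few usable spots, ...)."""


class EstimabilityError(LoopmaError):
    """The design matrix does not allow the requested estimation."""


class ParameterError(LoopmaError):
    """Invalid analysis parameter (k > n, level outside (0,1), ...)."""


class ConfigError(LoopmaError):
    """Invalid simulation or pipeline configuration."""


class InputError(LoopmaError):
    """Inconsistent inputs to an evaluation or pipeline stage."""
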