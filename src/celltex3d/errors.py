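"""Exception hierarchy shared across the pipeline stages."""


class CellTexError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(CellTexError, ValueError):
    """A parameter violates its contract; the message names the field."""


class FormatError(CellTexError, ValueError):
    """A file on disk does not match the expected format."""


class DegenerateInputError(CellTexError, ValueError):
    """Input is structurally valid but degenerate (blank image, empty mask...)."""


class EmptyResultError(CellTexError, RuntimeError):
    """An operation completed but produced no usable result (e.g. no foreground)."""


class UndefinedMetricError(CellTexError, ValueError):
    """A metric is mathematically undefined for this input (e.g. empty mask union)."""


class EmptyGLCMError(CellTexError, ValueError):
    """A co-occurrence matrix holds zero valid pixel pairs; features refuse it."""


class ContractError(CellTexError, ValueError):
    """An inter-stage contract is violated (unnormalized GLCM, missing labels...)."""
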