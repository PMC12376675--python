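"""Exception hierarchy shared across the pipeline."""


class SECircuitError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SECircuitError):
    """A text input (BED, bedGraph, TSV) could not be parsed."""


class InvalidParameterError(SECircuitError, ValueError):
    """A parameter violates its documented domain."""


class DegenerateInputError(SECircuitError):
    """Input is structurally valid but carries no usable signal."""


class GenerationError(SECircuitError):
    """The synthetic generator could not satisfy its placement constraints."""


class StageError(SECircuitError):
    """A pipeline stage is missing a dependency artifact."""
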