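"""Exceptions shared across the pipeline."""


class GrexPipeError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(GrexPipeError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class InvalidInputError(GrexPipeError, ValueError):
    """An input table or vector violates a precondition."""


class EmptyResultError(GrexPipeError):
    """A filtering step removed every record."""


class CollinearityError(GrexPipeError):
    """Design columns are (numerically) linearly dependent."""


class UntestableGeneError(GrexPipeError):
    """A gene cannot be tested (zero predicted-expression variance)."""


class LookupError_(GrexPipeError, KeyError):
    """A requested variant or gene is absent from the reference."""
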