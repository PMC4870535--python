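"""Exception hierarchy for the ticnet pipeline.

Every stage raises a subclass of :class:`TicnetError`, so callers (CLI,
pipeline driver) can distinguish user errors from internal contract
violations.
"""


class TicnetError(Exception):
    """Base class for all ticnet errors."""


class ConfigError(TicnetError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(TicnetError):
    """Input table does not have the expected columns/sample design."""


class ValidationError(TicnetError):
    """Input data violates an invariant (negative intensity, bad COG letter...)."""


class ParseError(TicnetError):
    """Malformed input file; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class InsufficientDataError(TicnetError):
    """Too few observations to compute the requested statistic."""


class DegeneratePopulationError(TicnetError):
    """A ratio population has zero spread and cannot be normalized."""

    def __init__(self, population: str):
        super().__init__(
            f"population {population!r} is constant; cannot normalize to unit sd"
        )
        self.population = population


class UnsupportedDesignError(TicnetError):
    """Design other than two states x two replicates per comparison."""


class AlignmentError(TicnetError):
    """Protein sets of two per-protein tables do not match."""


class PipelineError(TicnetError):
    """A pipeline stage failed; wraps the original error with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original
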