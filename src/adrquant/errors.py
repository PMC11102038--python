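"""Exception types raised across the pipeline."""
from __future__ import annotations


class AdrquantError(Exception):
    """Base class for package errors."""


class ConfigError(AdrquantError, ValueError):
    """Invalid configuration (parameter vectors, thresholds, periods)."""


class UndefinedResultError(AdrquantError, ArithmeticError):
    """A statistic is undefined for the given input (e.g. ROR with an
    empty off-diagonal and zero-cell correction disabled)."""


class UndefinedDistributionError(AdrquantError, ValueError):
    """No outcome-bearing reports: the conditional outcome distribution
    does not exist and the pair cannot be scored."""


class RangeError(AdrquantError, ValueError):
    """A value lies outside its admissible range."""


class PipelineError(AdrquantError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")

    def record(self) -> dict:
        """Machine-readable error record."""
        return {"stage": self.stage, "error": str(self)}
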