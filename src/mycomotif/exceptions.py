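"""Exception hierarchy shared across the package."""


class MycomotifError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MycomotifError, ValueError):
    """An input file violates its expected format (bad cell, duplicate id, ...)."""


class ValidationError(MycomotifError, ValueError):
    """Parsed data violate a semantic invariant (mixed guilds, unknown guild, ...)."""


class EmptyFilterError(MycomotifError, ValueError):
    """A filtering step removed everything the downstream pipeline needs."""


class RarefactionError(MycomotifError, ValueError):
    """A species has fewer reads than the requested rarefaction depth."""


class NullModelError(MycomotifError, RuntimeError):
    """Null-network sampling failed (retry cap exceeded on a pathological spec)."""


class UndefinedStatisticError(MycomotifError, ArithmeticError):
    """A statistic is undefined for this input (zero variance, n < 2, |r| = 1)."""


class StageError(MycomotifError, RuntimeError):
    """A pipeline stage failed; carries the stage name for the run log."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
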