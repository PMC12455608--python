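"""Exception hierarchy for g4rloop."""


class G4RloopError(Exception):
    """Base class for all g4rloop errors."""


class InvalidCodeError(G4RloopError, ValueError):
    """A PQS linker-length code is malformed (empty, non-digit, or zero digit)."""


class SequenceParseError(G4RloopError, ValueError):
    """A DNA sequence does not match the G-run / T-linker template."""


class ParameterError(G4RloopError, ValueError):
    """A rate constant or correction coefficient is out of its valid range."""


class NormalizationError(G4RloopError, ValueError):
    """A gel lane cannot be normalized (zero total channel signal)."""


class InsufficientDataError(G4RloopError, ValueError):
    """Too few observations for the requested estimate."""


class UnderDeterminedError(InsufficientDataError):
    """Fewer time points than free kinetic parameters."""


class ConfigError(G4RloopError, ValueError):
    """A generator or pipeline configuration is invalid."""


class TableFormatError(G4RloopError, ValueError):
    """A delimited-text table violates its documented schema."""


class PipelineError(G4RloopError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
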