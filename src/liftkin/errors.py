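"""Exception hierarchy shared across the pipeline stages."""


class LiftkinError(Exception):
    """Base class for all liftkin errors."""


class ConfigurationError(LiftkinError):
    """Invalid campaign, QC, or pipeline configuration."""


class InputError(LiftkinError):
    """An input value is outside its documented domain."""


class SimulationError(LiftkinError):
    """Non-finite or out-of-range parameters passed to a simulator."""


class MalformedTraceError(LiftkinError):
    """A transient record violates the flashlet-schedule contract."""


class DegenerateTraceError(LiftkinError):
    """A trace with no variable fluorescence (fm <= fo or fm <= 0)."""


class InsufficientSamplesError(LiftkinError):
    """Too few flashlet samples inside an integration window."""


class MissingBandError(LiftkinError):
    """The native spectrum does not cover the 400-800 nm grid."""


class MissingDarkError(LiftkinError):
    """No prior-night dark-current spectrum available."""


class EmptyLUTError(LiftkinError):
    """No usable gray-reference scans to build the PPFD lookup table."""


class SchemaError(LiftkinError):
    """Column mismatch between a fitted model and new data."""


class StageError(LiftkinError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
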