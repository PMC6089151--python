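"""Exception hierarchy for the eaccd package."""


class EaccdError(Exception):
    """Base class for all errors raised by eaccd."""


class NoEventsError(EaccdError):
    """Raised when a computation needs at least one observed event."""


class NoComparablePairsError(EaccdError):
    """Raised when the concordance index is undefined (no comparable pairs)."""


class PipelineError(EaccdError):
    """Failure of a named stage of the prognostic-system pipeline."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
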