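"""Package-specific error types."""


class CpcrQuantError(Exception):
    """Base class for all package errors."""


class BandShortfallError(CpcrQuantError):
    """Fewer detectable peaks in a lane than bands expected."""


class InsufficientDataError(CpcrQuantError):
    """Too few usable dilution points for a calibration line."""


class InvalidTitrationError(CpcrQuantError):
    """Calibration slope is non-negative or too shallow: no competition signal."""


class MissingBlankError(CpcrQuantError):
    """Blank correction requested but no blank syringes available."""


class StageError(CpcrQuantError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
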