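"""Exception hierarchy shared across the pipeline stages."""


class ShhScreenError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(ShhScreenError):
    """Invalid simulation or pipeline configuration."""


class PlateError(ShhScreenError):
    """Plate-level normalization failure (e.g. zero or non-finite plate median)."""


class ScreenError(ShhScreenError):
    """Screen-level scoring failure (e.g. degenerate z-score denominator)."""


class AssayError(ShhScreenError):
    """Secondary-assay statistics failure."""


class DosageError(ShhScreenError):
    """Dosage-expression computation failure."""


class PrioritizeError(ShhScreenError):
    """Candidate-integration failure."""


class FormatError(ShhScreenError):
    """Unparseable or inconsistent input file."""


class PipelineError(ShhScreenError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
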