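"""Exception hierarchy shared across pipeline stages."""


class SnpclustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SnpclustError):
    """Invalid configuration: bad column mapping, unknown phenotype label,
    threshold out of range, missing input file."""


class StageError(SnpclustError):
    """A pipeline stage failed at run time; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
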