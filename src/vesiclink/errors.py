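"""Exception hierarchy."""


class VesiclinkError(Exception):
    """Base class for all package errors."""


class FormatError(VesiclinkError, ValueError):
    """Malformed input file (bad coordinates, scores, duplicate ids...)."""


class ConfigError(VesiclinkError, ValueError):
    """Invalid run configuration (missing paths, thresholds out of range)."""


class PipelineError(VesiclinkError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
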