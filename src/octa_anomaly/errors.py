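"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A config object violates its invariants."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
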