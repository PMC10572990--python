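"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Malformed data: bad rows, out-of-range values, schema violations."""


class ConfigurationError(ValueError):
    """Inconsistent configuration: unknown labels, missing comparisons."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
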