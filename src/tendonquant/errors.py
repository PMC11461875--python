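"""Exception hierarchy for the quantification pipeline."""


class PipelineError(Exception):
    """Base class for all pipeline-specific errors."""


class ValidationError(PipelineError, ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(PipelineError):
    """The run configuration or file layout is inconsistent."""


class GenerationError(PipelineError):
    """Synthetic-image generation could not satisfy the requested layout."""
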