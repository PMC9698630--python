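"""Exception hierarchy shared across the pipeline stages."""


class RapafluxError(Exception):
    """Base class for all package errors."""


class ValidationError(RapafluxError):
    """A domain object violates one of its structural invariants."""


class NamedEntityError(ValidationError):
    """A metabolite / reaction / pathway name is not known to the receiving object."""


class FormatError(RapafluxError):
    """A file on disk does not conform to the expected dialect."""


class EmptyInputError(RapafluxError):
    """An operation received a degenerate (zero-sample / zero-variable) input."""


class ParameterError(RapafluxError):
    """An operation parameter is out of its documented range."""


class ConvergenceError(RapafluxError):
    """An iterative estimator failed to converge."""


class DegenerateResponseError(RapafluxError):
    """The response (Y) passed to a latent-variable fit carries no variance."""


class ConfigurationError(RapafluxError):
    """A pipeline or model configuration is inconsistent."""


class SchemaError(FormatError):
    """A serialized metabolic model violates its JSON schema."""


class NormalizationError(RapafluxError):
    """A quantity needed as a normalizer (e.g. a wild-type rate) is nonpositive."""


class StageError(RapafluxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
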