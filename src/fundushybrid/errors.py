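"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An operation received arguments violating its contract."""


class DegenerateInputError(InvalidArgumentError):
    """Input carries no usable signal (e.g. zero-variance matrix fed to PCA)."""


class BackboneUnavailableError(RuntimeError):
    """A requested pretrained backbone cannot be loaded in this environment."""
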