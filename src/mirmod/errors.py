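"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or schema."""


class FitError(RuntimeError):
    """Raised when a model or distribution cannot be fitted on the given data."""
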