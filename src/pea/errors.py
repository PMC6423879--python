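"""Exception types distinguishing bad input from numerical failure."""


class InputError(ValueError):
    """Raised when user-supplied data violates a precondition (shapes,
    finiteness, missing classes, malformed files)."""


class NumericalError(RuntimeError):
    """Raised when a linear-algebra step fails (non-positive-definite
    working covariance, singular normal equations, non-finite update)."""
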