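"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A model or run configuration violates an invariant (e.g. non-PSD IIV covariance)."""


class EstimationError(RuntimeError):
    """An estimation step failed (terminal-slope regression, optimizer non-convergence, ...)."""
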