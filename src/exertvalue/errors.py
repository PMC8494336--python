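"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(ValueError):
    """A parameter combination is internally inconsistent (e.g. a degenerate
    controller denominator), as opposed to a single bad input value."""
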