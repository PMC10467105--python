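"""Exception types shared across the package."""


class SigconnError(Exception):
    """Base class for all package errors."""


class DataError(SigconnError, ValueError):
    """Malformed or invariant-violating input data."""


class ConfigError(SigconnError, ValueError):
    """Invalid run configuration (missing paths, bad parameter values)."""


class FitError(SigconnError, RuntimeError):
    """Curve fitting failed or is degenerate."""
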