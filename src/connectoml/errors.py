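"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid configuration value or violated spec invariant."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class NoGroundTruthError(LookupError):
    """Raised when ground truth is requested from a user-supplied cohort."""
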