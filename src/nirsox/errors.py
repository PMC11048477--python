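"""Exception hierarchy for nirsox."""


class NirsoxError(Exception):
    """Base class for all package errors."""


class ValidationError(NirsoxError, ValueError):
    """An input violates a documented precondition (units, sign, shape)."""


class SingularSystemError(NirsoxError, ValueError):
    """The extinction system is rank deficient / too ill-conditioned to invert."""


class MissingChannelError(NirsoxError, KeyError):
    """A required (wavelength, separation) channel is absent from a recording."""


class SchemaError(NirsoxError, ValueError):
    """A worksheet file does not match the documented column schema."""
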