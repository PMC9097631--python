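"""Exception hierarchy shared across the package."""


class HemeprError(ValueError):
    """Base class for all domain errors raised by hemepr."""


class InvalidGTensorError(HemeprError):
    """g-tensor violates the preconditions of the one-hole analysis."""


class InvalidCoefficientsError(HemeprError):
    """Orbital coefficients cannot be mapped to a g-tensor."""


class DegenerateGError(HemeprError):
    """Two principal g-values coincide where a denominator requires them distinct."""


class ConfigurationError(HemeprError):
    """Missing or inconsistent user configuration (sigmas, seeds, windows...)."""


class FormatError(HemeprError):
    """Malformed or unsupported file content."""


class NyquistError(HemeprError):
    """Requested modulation frequency exceeds the Nyquist limit of the dwell time."""
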