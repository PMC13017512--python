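"""Exception hierarchy used across the package."""


class AdmixkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AdmixkitError, ValueError):
    """A file or record does not conform to the expected format."""


class DimensionError(AdmixkitError, ValueError):
    """Array or table dimensions are inconsistent."""


class InvariantError(AdmixkitError, ValueError):
    """A data-model invariant is violated (e.g. dosage exceeding ploidy)."""


class PopulationLookupError(AdmixkitError, KeyError):
    """A requested population label is absent from the panel."""


class EstimationError(AdmixkitError, RuntimeError):
    """A statistic cannot be estimated (e.g. zero usable sites)."""


class DegenerateError(EstimationError):
    """Input is degenerate for the requested computation (e.g. zero MAD)."""


class ConfigurationError(AdmixkitError, ValueError):
    """Invalid analysis configuration (thresholds, block sizes, model setup)."""


class InputError(AdmixkitError, ValueError):
    """Invalid numeric input (e.g. coordinates out of range)."""
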