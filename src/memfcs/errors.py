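"""Exception types shared across the package."""


class MemFCSError(Exception):
    """Base class for all package errors."""


class ConfigError(MemFCSError, ValueError):
    """Invalid simulation or analysis configuration."""


class CorrelationError(MemFCSError, ValueError):
    """Autocorrelation undefined or ill-posed for the given trace."""


class FitError(MemFCSError, RuntimeError):
    """Model fitting failed or was requested on unsuitable data."""


class CarpetError(MemFCSError, RuntimeError):
    """Carpet-level failure of the scanning-FCS pipeline."""


class ProfileError(MemFCSError, ValueError):
    """Line profile does not contain two usable membrane crossings."""


class FormatError(MemFCSError, ValueError):
    """Malformed input file."""
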