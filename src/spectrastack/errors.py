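"""Exception hierarchy shared across the package."""


class SpectraStackError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(SpectraStackError, ValueError):
    """Malformed spectra file or container (ragged rows, bad wavelength header...)."""


class ParameterError(SpectraStackError, ValueError):
    """Invalid user-supplied parameter or configuration."""


class DegenerateDataError(SpectraStackError, ValueError):
    """Numerically degenerate input (zero variance, zero regression slope...)."""


class ConsistencyError(SpectraStackError, ValueError):
    """Inconsistent metadata, e.g. conflicting labels within a replicate group."""


class StratificationError(SpectraStackError, ValueError):
    """Stratified folds cannot be constructed for the requested split."""
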