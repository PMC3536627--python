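"""Exception hierarchy shared across the package."""


class CisEvoError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CisEvoError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class InvalidSequenceError(CisEvoError, ValueError):
    """A DNA string contains characters outside {A, C, G, T} or has a bad length."""


class DegenerateLandscapeError(CisEvoError, ValueError):
    """All raw scores are equal; normalization is undefined."""


class NotABinderError(CisEvoError, ValueError):
    """The queried site has zero specificity in the given table."""


class LandscapeFormatError(CisEvoError, ValueError):
    """A landscape file violates the TSV contract (columns, row count, duplicates)."""


class IncompatibleParentsError(CisEvoError, ValueError):
    """Parents differ in gene count, URR length, signs, or initial state."""


class ConfigurationError(CisEvoError, ValueError):
    """Inconsistent simulation inputs (e.g. table count != gene count)."""


class DimensionError(CisEvoError, ValueError):
    """Vector or matrix dimensions do not agree."""


class FounderSearchError(CisEvoError, RuntimeError):
    """No viable founder found within the attempt cap."""


class ProgressTimeoutError(CisEvoError, RuntimeError):
    """Offspring acceptance stalled beyond the attempt cap."""


class DecompositionError(CisEvoError, ValueError):
    """Robustness decomposition undefined (total observed change is zero)."""


class BaselineError(CisEvoError, ValueError):
    """A random-network baseline is unusable (e.g. predicted value >= 1)."""


class GenerationError(CisEvoError, RuntimeError):
    """Failed to generate random individuals matching a requested property."""
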