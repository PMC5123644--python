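"""Exception hierarchy shared across the package."""


class SuzukiLoopError(Exception):
    """Base class for package errors."""


class DomainError(SuzukiLoopError, ValueError):
    """A value lies outside the experimental domain (names the offending variable)."""


class ConfigurationError(SuzukiLoopError, ValueError):
    """A campaign or design request is internally inconsistent."""


class FitError(SuzukiLoopError, RuntimeError):
    """A regression could not produce a usable model."""


class PlantError(SuzukiLoopError, RuntimeError):
    """The (real or simulated) reactor failed to return a measurement."""


class RankDeficientFitWarning(UserWarning):
    """The feature matrix was rank deficient; coefficients come from a pseudo-inverse."""
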