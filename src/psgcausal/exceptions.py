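"""Exception hierarchy for the pipeline.

Every failure class the command-line layer maps to a distinct exit code is a
subclass of :class:`PsgCausalError`.
"""


class PsgCausalError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InstabilityError(PsgCausalError):
    """A generative model is (or became) explosive: spectral radius >= 1."""

    exit_code = 4


class RankDeficientError(PsgCausalError):
    """A regression design matrix is rank deficient (e.g. constant channel)."""

    exit_code = 5


class ConvergenceError(PsgCausalError):
    """An iterative solver failed to reach its tolerance."""

    exit_code = 6


class WindowQuotaError(PsgCausalError):
    """The candidate grid was exhausted before the window quota was met."""

    exit_code = 7


class MissingManifestError(PsgCausalError):
    """A pipeline stage requires an upstream manifest that does not exist."""

    exit_code = 3


class ConfigError(PsgCausalError):
    """Invalid configuration value or unsupported option."""

    exit_code = 2
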