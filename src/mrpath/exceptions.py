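"""Exception hierarchy shared across the package."""


class MrpathError(Exception):
    """Base class for all package-specific errors."""


class DataError(MrpathError):
    """Invalid or unusable input data (empty file, empty SNP intersection...)."""


class ConfigError(MrpathError):
    """Invalid configuration: missing column, bad threshold, malformed config file."""


class EstimationError(MrpathError):
    """An estimator cannot be computed on the given input."""


class InsufficientInstrumentsError(EstimationError):
    """Too few SNPs for the requested estimator."""


class CollinearityError(EstimationError):
    """Rank-deficient exposure matrix in multivariable MR."""
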