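"""Exception hierarchy."""


class HeatmortError(Exception):
    """Base class for package errors."""


class ConfigurationError(HeatmortError, ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(HeatmortError, ValueError):
    """Invalid or insufficient input data."""


class FittingError(HeatmortError, RuntimeError):
    """Model fitting failed (non-convergence, too few observations...)."""


class RankDeficiencyError(FittingError):
    """Design matrix is rank deficient (collinear spline basis)."""


class EstimationError(HeatmortError, RuntimeError):
    """Iterative estimation failed to converge."""
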