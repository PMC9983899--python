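"""Exception hierarchy shared across the pipeline."""


class PushPullError(Exception):
    """Base class for package errors."""


class ConfigurationError(PushPullError):
    """A configuration object references unknown biomarkers or is malformed."""


class DegenerateInputError(PushPullError, ValueError):
    """Input too small or too degenerate for the requested operation."""


class NumericalError(PushPullError, RuntimeError):
    """Numerical degeneracy (singular innovation, overflowing dynamics, ...)."""


class EstimationError(PushPullError, RuntimeError):
    """Estimation failed (rank-deficient design, too many failed null fits)."""
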