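"""Exception hierarchy for the rwcea pipeline."""


class RwceaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RwceaError):
    """A simulation or run configuration field is invalid."""


class ValidationError(RwceaError):
    """Input data violate the documented schema or internal consistency."""


class EstimationError(RwceaError):
    """An estimator cannot be computed (separation, undefined weights, ...)."""


class DegenerateArmError(EstimationError):
    """An arm carries no usable observation time (e.g. everyone censored
    within the first interval), so censoring weights are undefined."""
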