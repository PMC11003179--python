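"""Exception hierarchy; each class maps to one CLI exit code."""


class SymptomNetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(SymptomNetError):
    """Input data or configuration is malformed."""

    exit_code = 2


class EstimationError(SymptomNetError):
    """A model-estimation stage (polychoric / glasso / centrality) failed."""

    exit_code = 3


class DegenerateItemError(EstimationError):
    """An item has fewer than two observed categories; correlations with it
    are undefined."""


class ResamplingError(SymptomNetError):
    """A bootstrap stage failed (too many replicate failures, infeasible
    subset sizes, or insufficient replicates for the requested percentiles)."""

    exit_code = 4
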