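"""Exception hierarchy for lipidmix.

All lipidmix errors derive from :class:`LipidmixError` so callers can catch
the package's failures with one clause while still distinguishing the
numerically meaningful ones (singular information matrices, empty design
regions, data-leakage in validation).
"""


class LipidmixError(Exception):
    """Base class for all lipidmix errors."""


class RegionEmptyError(LipidmixError):
    """The constrained mixture region contains no feasible point."""


class SamplingFailureError(LipidmixError):
    """Rejection sampling of the constrained region is too inefficient."""


class SingularInformationError(LipidmixError):
    """X'X is singular for the requested term set and design."""


class UnderDeterminedError(LipidmixError):
    """Fewer runs than model coefficients."""


class InfeasibleError(LipidmixError):
    """Fixed components or constraints make the problem infeasible."""


class DomainError(LipidmixError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class PredictionDomainError(LipidmixError):
    """A transformed-scale prediction cannot be mapped back to the raw scale."""


class ValidationLeakageError(LipidmixError):
    """A hold-out run was present in the training design."""


class MalformedRowError(LipidmixError):
    """A design file row is neither a percentage nor a proportion row."""


class GenerationError(LipidmixError):
    """Synthetic response generation rejected too many draws."""


class GoalError(LipidmixError, ValueError):
    """A desirability goal has inconsistent bounds or parameters."""
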