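"""Exception hierarchy.

All errors raised by the package derive from :class:`MotifDimError` so callers
can catch the package's failures in one clause while still distinguishing
parameter mistakes from genuine dynamical pathologies (instability,
divergent resummation).
"""


class MotifDimError(Exception):
    """Base class for all motifdim errors."""


class ParameterError(MotifDimError, ValueError):
    """An argument is outside its admissible range."""


class ValidationError(MotifDimError, ValueError):
    """An input object violates a structural invariant (shape, symmetry, ...)."""


class FeasibilityError(ParameterError):
    """A requested motif-parameter combination cannot be realized.

    The message names the offending parameter(s).
    """


class InstabilityError(MotifDimError, RuntimeError):
    """The effective connectivity has spectral radius >= 1.

    Linear-response covariances do not exist for such networks; the offending
    radius is carried on the ``spectral_radius`` attribute.
    """

    def __init__(self, spectral_radius: float, message: str | None = None):
        self.spectral_radius = float(spectral_radius)
        super().__init__(
            message
            or f"network is linearly unstable (spectral radius "
            f"{self.spectral_radius:.4f} >= 1)"
        )


class DivergenceError(MotifDimError, RuntimeError):
    """The resummed chain-cumulant series is supercritical (sum >= 1).

    This is the motif-level signature of linear instability: the geometric
    resummation factor (1 - sum_n N^n kappa_n)^-1 would be negative or
    infinite.
    """

    def __init__(self, chain_sum: float):
        self.chain_sum = float(chain_sum)
        super().__init__(
            f"chain-cumulant series sum {self.chain_sum:.4f} >= 1: "
            "the motif resummation diverges (predicted instability)"
        )


class ModelValidityError(MotifDimError, RuntimeError):
    """The linearized-rate approximation broke down during simulation."""
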