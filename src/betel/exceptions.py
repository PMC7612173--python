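"""Exception hierarchy.

``BetelError`` is the common base; user-facing entry points map
``ValidationError`` to a usage error and everything else to a numerical
failure.
"""


class BetelError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(BetelError):
    """Malformed input data or configuration."""


class FeasibilityError(BetelError):
    """The LP feasibility check failed for a reason other than infeasibility."""


class DualSolveError(BetelError):
    """The Newton solve of the ETEL dual problem failed."""

    def __init__(self, message, residual=None, iterations=None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class NonConvergenceError(DualSolveError):
    """Dual iteration did not reach the tolerance within the budget."""


class SingularJacobianError(DualSolveError):
    """The dual Hessian (weighted moment covariance) is rank deficient."""


class PositivityError(BetelError):
    """A fitted or supplied selection probability is numerically zero."""


class MEstimationError(BetelError):
    """Estimating-equation solve failed."""

    def __init__(self, message, theta_last=None, residual=None):
        super().__init__(message)
        self.theta_last = theta_last
        self.residual = residual


class SamplingError(BetelError):
    """Posterior sampling failed (e.g. no feasible particles, tiny ESS)."""
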