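"""Exception hierarchy.

All user-input problems derive from :class:`InputError` (a ``ValueError``),
so callers can distinguish bad study configurations from numerical failures
(:class:`ConvergenceError`, a ``RuntimeError``).
"""


class InputError(ValueError):
    """Invalid study configuration: bad dimensions, signs, or ranges."""


class UnsupportedMethodError(InputError):
    """The requested analytic method does not apply to this configuration.

    Raised e.g. when an analytic power function (derived under normal
    predictors) is asked to handle a non-normal predictor family.
    """


class SingularDesignError(InputError):
    """The design matrix is rank deficient; least squares is not unique."""


class NoSolutionError(InputError):
    """No finite sample size can achieve the request (zero effect size)."""


class ConvergenceError(RuntimeError):
    """A numerical routine failed to reach its accuracy target.

    Raised instead of returning a silently inaccurate result.
    """
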