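"""Package-level error types."""


class ApproximationInvalidError(RuntimeError):
    """An asymptotic posterior approximation broke down: indefinite
    Hessian at the expansion/maximisation point, a failed inner
    maximisation, or a non-positive approximated moment."""


class OracleFailureError(RuntimeError):
    """The quadrature oracle could not certify its result to the
    requested tolerance (non-integrable posterior or slow convergence);
    raised instead of returning a silently wrong value."""
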