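"""Exception hierarchy for dacrank."""


class DacrankError(Exception):
    """Base class for all dacrank errors."""


class ValidationError(DacrankError, ValueError):
    """Invalid parameters or configuration (e.g. non-positive scale)."""


class ContractError(DacrankError, TypeError):
    """An operation was called with a density family it does not accept."""


class DegeneratePosteriorError(DacrankError):
    """The prior excludes all likelihood mass: the posterior has zero mass."""


class QuadratureError(DacrankError):
    """Adaptive quadrature failed to converge to the requested tolerance."""

    def __init__(self, message: str, error_estimate: float | None = None):
        super().__init__(message)
        self.error_estimate = error_estimate
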