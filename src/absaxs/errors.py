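"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`AbsaxsError`
so callers can catch package failures without masking programming errors.
"""


class AbsaxsError(Exception):
    """Base class for all package errors."""


class ValidationError(AbsaxsError, ValueError):
    """Input violates a documented precondition."""


class FormatError(AbsaxsError, ValueError):
    """A file could be opened but not understood."""


class FitError(AbsaxsError, RuntimeError):
    """A regression or optimisation failed to converge to a usable answer."""


class PlacementError(AbsaxsError, RuntimeError):
    """A geometric placement could not be satisfied within bounded retries."""


class ClashRejection(AbsaxsError):
    """A candidate assembly violated the hard-sphere clash filter.

    Carries the offending minimum inter-unit distance so callers can report it.
    Raised by individual assembly operations; ensemble builders catch it and
    count the rejection rather than aborting.
    """

    def __init__(self, min_distance: float, threshold: float, context: str = ""):
        self.min_distance = float(min_distance)
        self.threshold = float(threshold)
        self.context = context
        msg = (
            f"clash: minimum inter-unit distance {min_distance:.3f} A "
            f"< {threshold:.3f} A"
        )
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class SamplingError(AbsaxsError, RuntimeError):
    """Monte Carlo sampling exhausted its attempt budget.

    Carries an acceptance-rate diagnostic.
    """

    def __init__(self, message: str, attempts: int, accepted: int):
        self.attempts = attempts
        self.accepted = accepted
        rate = accepted / attempts if attempts else 0.0
        super().__init__(f"{message} (accepted {accepted}/{attempts}, rate {rate:.4f})")
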