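"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PerifractError` so that the
orchestrator can abort with the stage name and the offending record.
"""


class PerifractError(Exception):
    """Base class for all pipeline errors."""


class InputError(PerifractError):
    """Invalid input to an operation (dimension mismatch, out-of-bounds spec...)."""


class SizingError(InputError):
    """An image or fixture is too small (or incompatibly sized) for the request."""


class ConfigurationError(PerifractError):
    """An invalid run or scenario configuration."""


class RegistrationError(PerifractError):
    """Registration is undefined for the given pair (e.g. constant image)."""


class RoiPlacementError(PerifractError):
    """No admissible ROI placement exists; carries the violated constraints."""

    def __init__(self, side: str, constraints: list[str]):
        self.side = side
        self.constraints = list(constraints)
        super().__init__(
            f"no admissible {side} ROI placement: " + "; ".join(self.constraints)
        )


class EmptyMaskError(PerifractError):
    """Box-counting dimension is undefined on an empty mask (not zero)."""


class DegenerateDesignError(PerifractError):
    """The longitudinal design cannot identify the requested effects."""
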