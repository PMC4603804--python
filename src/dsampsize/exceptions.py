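"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An input violates its documented domain (probabilities, signs, ranges)."""


class FeasibilityError(InvalidInputError):
    """A margin or half-width is below the minimum attainable given the prior SE.

    Attributes
    ----------
    minimum : float
        The smallest feasible margin/half-width for the supplied design.
    """

    def __init__(self, message: str, minimum: float):
        super().__init__(message)
        self.minimum = minimum


class EstimationError(RuntimeError):
    """D estimation could not proceed (e.g. fewer than two events)."""


class SimulationError(RuntimeError):
    """The exact-count simulator could not assemble the requested dataset."""
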