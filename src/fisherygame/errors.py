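"""Exception and warning types shared across the package."""


class ParameterError(ValueError):
    """A parameter is outside its admissible domain."""


class NotViableError(RuntimeError):
    """Fishing is not economically viable: the cost of the first unit of
    effort already exceeds its revenue (c' >= B'*P*q)."""


class DegenerateEncounterWarning(UserWarning):
    """The regulated effort meets or exceeds the profit-maximizing total
    effort, so a cheater in a mixed encounter would contribute negative
    effort; it is clipped to zero."""


class DegenerateGameError(RuntimeError):
    """Two payoffs that the outcome classification compares are equal to
    within tolerance; the outcome is not well defined."""


class NoInteriorEquilibriumError(RuntimeError):
    """The payoff matrix admits no interior equilibrium (the equal-fitness
    equation is degenerate)."""


class NoBoundaryError(RuntimeError):
    """The requested outcome transition does not occur along the scanned
    growth-rate interval."""


class IntegrationError(RuntimeError):
    """Replicator integration received non-finite payoffs or failed."""
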