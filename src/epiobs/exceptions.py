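"""Exception types shared across the package."""


class EpiobsError(ValueError):
    """Base class for all model-level errors."""


class DivergenceError(EpiobsError):
    """An age-integral does not converge (no absorbing hazard on the stage)."""


class DegenerateModelError(EpiobsError):
    """A parameter combination implies no transmission or no defined quantity."""


class InconsistentParametersError(EpiobsError):
    """Reduced-form parameters violate a closure identity beyond tolerance."""


class FixtureValidationError(EpiobsError):
    """A disease fixture failed its cross-relation consistency checks."""


class StabilityError(EpiobsError):
    """The simulation step is too coarse for the fastest hazard."""
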