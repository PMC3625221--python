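"""The symptom-based ("observable") transmission model.

Infected individuals all start in an asymptomatic stage ``J_A`` (indexed by
infection-age ``tau``); a fraction ``alpha`` develops symptoms and moves to a
symptomatic stage ``J_S`` (indexed by disease-age ``sigma`` since onset), the
rest recover without ever showing symptoms.  The basic reproduction number
decomposes as

    R0 = R1 + alpha * R2

where R1 is the expected number of secondary cases produced during the
asymptomatic period (experienced by every infected individual) and R2 the
expected number produced during the symptomatic period (experienced only by
the fraction alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DegenerateModelError
from .kernels import (
    AgeRate,
    default_age_max,
    expected_reproduction_integral,
    survival_from_hazards,
)

__all__ = [
    "ObservableParams",
    "ObservableKernels",
    "r0_observable",
    "asymptomatic_share",
    "observable_params_from_kernels",
]


@dataclass(frozen=True)
class ObservableParams:
    """Reduced-form parameters of the symptom-based model.

    Attributes
    ----------
    R1
        Secondary cases per case during the asymptomatic period.
    R2
        Secondary cases per symptomatic case over the symptomatic period.
    alpha
        Probability of developing symptoms given infection.
    S0
        Initial susceptible pool (only the linearized dynamics use it).
    """

    R1: float
    R2: float
    alpha: float
    S0: float = 1.0

    def __post_init__(self) -> None:
        if self.R1 < 0 or self.R2 < 0:
            raise ValueError("R1 and R2 must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass(frozen=True)
class ObservableKernels:
    """Mechanistic (age-dependent rate) backing of the symptom-based model.

    ``beta_A(tau)`` and ``beta_S(sigma)`` are the transmission rates of
    asymptomatic and symptomatic cases; ``eta(tau)`` the symptom-onset rate;
    ``gamma_A(tau)`` and ``gamma_S(sigma)`` the recovery rates of the two
    stages.
    """

    beta_A: AgeRate
    beta_S: AgeRate
    eta: AgeRate
    gamma_A: AgeRate
    gamma_S: AgeRate
    S0: float = 1.0


def r0_observable(params: ObservableParams) -> float:
    """Basic reproduction number ``R1 + alpha * R2``."""
    return params.R1 + params.alpha * params.R2


def asymptomatic_share(params: ObservableParams) -> float:
    """Proportion of all secondary transmissions that are asymptomatic.

    ``theta = R1 / (R1 + alpha * R2)``; undefined when R0 = 0.
    """
    r0 = r0_observable(params)
    if r0 <= 0.0:
        raise DegenerateModelError("asymptomatic share is undefined when R0 = 0")
    return params.R1 / r0


def observable_params_from_kernels(
    beta_A: AgeRate,
    beta_S: AgeRate,
    eta: AgeRate,
    gamma_A: AgeRate,
    gamma_S: AgeRate,
    grid_step: float = 0.01,
    age_max: float | None = None,
    S0: float = 1.0,
) -> ObservableParams:
    """Reduced-form parameters from age-dependent rates.

    R1 = int beta_A(tau) exp(-int (eta + gamma_A)) dtau,
    alpha = int eta(tau) exp(-int (eta + gamma_A)) dtau  (competing risks),
    R2 = int beta_S(sigma) exp(-int gamma_S) dsigma.

    For constant rates these are ``beta_A/(eta+gamma_A)``,
    ``eta/(eta+gamma_A)`` and ``beta_S/gamma_S``.  Raises
    :class:`~epiobs.exceptions.DivergenceError` if a stage lacks an absorbing
    hazard (infinite-mass kernel).
    """
    asym_max = age_max if age_max is not None else default_age_max([eta, gamma_A])
    sym_max = age_max if age_max is not None else default_age_max([gamma_S])
    surv_A = survival_from_hazards([eta, gamma_A], grid_step, asym_max)
    surv_S = survival_from_hazards([gamma_S], grid_step, sym_max)
    r1 = expected_reproduction_integral(beta_A, surv_A)
    alpha = expected_reproduction_integral(eta, surv_A)
    r2 = expected_reproduction_integral(beta_S, surv_S)
    # quadrature can overshoot a probability of 1 by O(step^2)
    return ObservableParams(R1=r1, R2=r2, alpha=min(alpha, 1.0), S0=S0)
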