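"""The contagiousness-based ("unobservable") SEIR-type model.

Infected individuals pass through a latent stage ``E`` and then acquire
infectiousness, splitting at that moment into symptomatic infectious (``I_S``,
probability ``k``) and asymptomatic infectious (``I_A``) cases, the latter
transmitting at a relative rate ``m <= 1``.  Its basic reproduction number is
the symptom-probability-weighted average

    R0 = k * R4 + (1 - k) * R3,        R3 = m * R4 under shared contact rates,

with R4 (R3) the expected secondary cases of a symptomatic (asymptomatic)
infectious case.  Because the E -> I transition is driven by contagiousness,
not by symptom onset, this model has no notion of pre-symptomatic
transmission.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateModelError
from .kernels import AgeRate, default_age_max, stage_occupancy
from .observable import ObservableParams, r0_observable

__all__ = [
    "UnobservableParams",
    "UnobservableKernels",
    "r0_unobservable",
    "calibrate_to_observable",
    "unobservable_params_from_kernels",
]


@dataclass(frozen=True)
class UnobservableParams:
    """Reduced-form parameters of the SEIR-type model.

    ``m`` records the relative infectiousness of asymptomatic cases; when the
    parameter set is produced by calibration, ``R3 = m * R4`` holds exactly.
    """

    R3: float
    R4: float
    k: float
    m: float | None = None

    def __post_init__(self) -> None:
        if self.R3 < 0 or self.R4 < 0:
            raise ValueError("R3 and R4 must be nonnegative")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must lie in [0, 1]")
        if self.m is not None and not 0.0 <= self.m <= 1.0:
            raise ValueError("m must lie in [0, 1]")


@dataclass(frozen=True)
class UnobservableKernels:
    """Mechanistic backing: latency rate ``epsilon(tau)``, transmission rate
    ``beta(tau)``, recovery rates ``kappa_A``/``kappa_S`` and the split
    probability ``k``; asymptomatic transmission is scaled by ``m``."""

    beta: AgeRate
    epsilon: AgeRate
    kappa_A: AgeRate
    kappa_S: AgeRate
    k: float
    m: float = 1.0
    S0: float = 1.0


def r0_unobservable(params: UnobservableParams) -> float:
    """Basic reproduction number ``k * R4 + (1 - k) * R3``.

    The symptom probability k weights the symptomatic reproduction number R4;
    the asymptomatic fraction (1 - k) weights R3.
    """
    return params.k * params.R4 + (1.0 - params.k) * params.R3


def calibrate_to_observable(obs: ObservableParams, m: float) -> UnobservableParams:
    """SEIR-type parameters sharing the symptom-based model's threshold.

    Sets ``k = alpha`` (identical symptom probabilities) and solves
    ``k*R4 + (1-k)*m*R4 = R0_obs`` for R4, so that both models have exactly
    the same basic reproduction number in the absence of vaccination.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    k = obs.alpha
    weight = k + (1.0 - k) * m
    if weight <= 0.0:
        raise DegenerateModelError(
            "alpha = 0 and m = 0 leaves no infectious class: cannot calibrate"
        )
    r4 = r0_observable(obs) / weight
    return UnobservableParams(R3=m * r4, R4=r4, k=k, m=m)


def unobservable_params_from_kernels(
    kernels: UnobservableKernels,
    grid_step: float = 0.01,
    age_max: float | None = None,
) -> UnobservableParams:
    """Reduced-form R3, R4 from the age-dependent rates.

    A symptomatic case contributes ``R4 = int beta(tau) * P_S(tau) dtau``
    where ``P_S`` is the probability of being in I_S at infection-age tau
    (latency exit at some age s, then survival under kappa_S); R3 is the
    analogue with kappa_A, scaled by m.
    """
    kk = kernels
    if age_max is None:
        age_max = default_age_max([kk.epsilon]) + max(
            default_age_max([kk.kappa_A]), default_age_max([kk.kappa_S])
        )
    n = int(np.ceil(age_max / grid_step))
    ages = np.arange(n + 1) * grid_step
    eps = kk.epsilon(ages)
    surv_e = np.exp(
        -np.concatenate(([0.0], np.cumsum(0.5 * (eps[1:] + eps[:-1]) * np.diff(ages))))
    )
    entry = eps * surv_e
    occ_s = stage_occupancy(entry, kk.kappa_S, ages)
    occ_a = stage_occupancy(entry, kk.kappa_A, ages)
    beta = kk.beta(ages)
    r4 = float(np.trapezoid(beta * occ_s, ages))
    r3 = kk.m * float(np.trapezoid(beta * occ_a, ages))
    return UnobservableParams(R3=r3, R4=r4, k=kk.k, m=kk.m)
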